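# End-to-end pipeline run: characterize the suspended-cylinder variant and
# analyse a synthetic field with its flow structure (circular loci across
# the span under the cylinder, elongated outside it).
well: sc_2mm
scenario:
  name: sc_like
  n_radii: 20
  n_azimuths: 8
  n_samples: 360
profile_bins: 25
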