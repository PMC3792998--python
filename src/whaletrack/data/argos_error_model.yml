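# Per-location-class scaled-t error parameters for Argos fixes.
#
# nu: degrees of freedom (smaller = heavier tails), tau_*: scale in decimal
# degrees. These defaults follow the published magnitude ordering of Argos
# class accuracies (class 3 best, ~0.25 km scale; class B worst, ~2.5 km,
# with much heavier tails). They are configuration, not constants: edit this
# file (or point the config at another one) to use your own estimates.
classes:
  "3": {nu: 10.0, tau_lon: 0.0025, tau_lat: 0.0020}
  "2": {nu: 8.0, tau_lon: 0.0040, tau_lat: 0.0030}
  "1": {nu: 6.0, tau_lon: 0.0080, tau_lat: 0.0060}
  "0": {nu: 4.0, tau_lon: 0.0200, tau_lat: 0.0150}
  "A": {nu: 4.0, tau_lon: 0.0120, tau_lat: 0.0100}
  "B": {nu: 3.0, tau_lon: 0.0250, tau_lat: 0.0200}
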