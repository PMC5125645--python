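# Default class-conditional SHAPE reactivity distributions.
#
# Unpaired nucleotides follow a heavy-right-tailed generalized extreme value
# distribution (high reactivities common); stacked and helix-end nucleotides
# follow low-mean exponentials, with helix-terminal pairs somewhat more
# reactive than interior ones. These defaults emulate the qualitative shape
# of probing data on large ribosomal RNAs; re-fit them to your own
# (structure, reactivity) training data with
# esdfold.shape_sim.fit_distribution_set. See docs/methods.md.
unpaired:
  family: gev
  params: [-0.25, 0.55, 0.45]   # scipy genextreme: shape c, loc, scale
stacked:
  family: exponential
  params: [0.07]                # scale (mean reactivity)
helix_end:
  family: exponential
  params: [0.25]
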