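"""Score a prediction against a reference structure at base-pair level."""

from esdfold import parse_dotbracket, score

reference = parse_dotbracket("((((....))))..((....))")
prediction = parse_dotbracket("((((....))))..........")

report = score(prediction, reference)
print(f"TP = {report.tp}, FP = {report.fp}, FN = {report.fn}")
print(f"Sn = {report.sn:.3f}  PPV = {report.ppv:.3f}  Accuracy = {report.accuracy:.3f}")
# Sensitivity is the fraction of reference pairs recovered; PPV the fraction
# of predicted pairs that are correct; Accuracy their mean. Here the first
# helix is found (TP=4) and the second missed (FN=2): Sn = 4/6, PPV = 1.
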