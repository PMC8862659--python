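"""Score a detected community profile against a known mock community.

Builds a small observed signal (assigned bases per species) with one
false positive and one low-abundance miss, and calls TP/FP/FN at a
detection threshold.
"""

from lcabin.comparer import evaluate_mock

reference = {  # defined mixture: species -> relative abundance
    "Thermus aquaticus": 0.40,
    "Escherichia coli": 0.35,
    "Halobacterium salinarum": 0.20,
    "Salmonella bongori": 0.05,
}
observed = {  # assigned bases per detected species
    "Thermus aquaticus": 412_000.0,
    "Escherichia coli": 355_000.0,
    "Halobacterium salinarum": 198_000.0,
    "Salmonella bongori": 1_200.0,      # below threshold: missed
    "Pseudomonas aeruginosa": 25_000.0,  # spurious detection
}

evaluation = evaluate_mock(observed, reference, detection_threshold=5_000.0)
print(f"threshold: {evaluation.detection_threshold:g} assigned bases")
print(f"true positives : {sorted(evaluation.true_positive)}")
print(f"false positives: {sorted(evaluation.false_positive)}")
print(f"false negatives: {sorted(evaluation.false_negative)}")

# A false negative is a mixture member whose signal stayed below the
# threshold; a false positive is a detection absent from the mixture.
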