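"""The overlap-score benchmark: how predictions are matched to references.

A prediction A matches a reference complex B when
OS(A, B) = |A∩B|² / (|A|·|B|) exceeds 0.20.  Precision counts matched
predictions, recall counts matched references, and the f-measure is their
harmonic mean.  Sets smaller than 4 are excluded: they match too easily by
chance.
"""

from ppicomplex import ComplexSet, f_measure, overlap_score, score_predictions

reference = ComplexSet.from_iterable([
    ("proteasome_lid", {"p1", "p2", "p3", "p4", "p5"}),
    ("mediator_head", {"m1", "m2", "m3", "m4"}),
    ("exosome_core", {"e1", "e2", "e3", "e4", "e5", "e6"}),
])

predictions = [
    {"p1", "p2", "p3", "p4", "p5"},          # exact hit
    {"m1", "m2", "m3", "x"},                 # partial hit
    {"b1", "b2", "b3", "b4"},                # spurious cluster
]

for p in predictions:
    best = max(overlap_score(p, m) for _, m in reference)
    print(f"prediction {sorted(p)}: best overlap score {best:.3f} "
          f"{'MATCH' if best > 0.20 else 'no match'}")

report = score_predictions(predictions, reference, overlap_threshold=0.20)
print("\n" + report.summary())
print("\nthe f-measure is the harmonic mean, e.g. "
      f"f(0.333, 0.491) = {f_measure(0.333, 0.491):.3f}")
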