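"""Benchmark a predicted annotation against a reference.

Compares a toy prediction with a reference annotation under a family
correspondence map (for renamed families), reporting coverage,
classification accuracy and the missed entries with reason tags.
"""

from tfannot.benchmark import CorrespondenceMap, evaluate, missed_report

reference = {
    "p1": "WRKY", "p2": "WRKY", "p3": "MYB", "p4": "G2-like",
    "p5": "HD-ZIP", "p6": "C2H2", "p7": "ARF", "p8": "NAC",
}
predicted = {
    "p1": "WRKY", "p2": "WRKY", "p3": "MYB", "p4": "G2-like/GLK",
    "p5": "HB-other", "p7": "ARF",
}
corr = CorrespondenceMap({
    "WRKY": ["WRKY"], "MYB": ["MYB"], "G2-like": ["G2-like/GLK"],
    "HD-ZIP": ["HD-ZIP"], "C2H2": ["C2H2"], "ARF": ["ARF"], "NAC": ["NAC"],
})

rep = evaluate(predicted, reference, corr)
print(f"reference: {rep.n_reference}, predicted: {rep.n_predicted}, overlap: {rep.n_overlap}")
print(f"coverage fraction: {rep.coverage_fraction:.3f}")
print(f"accuracy (overlap denominator): {rep.accuracy_fraction:.3f}")
print(f"accuracy (reference denominator): {rep.accuracy_vs_reference:.3f}\n")

missed = missed_report(
    predicted, reference,
    reasons={"p6": "FD_veto", "p8": "below_cutoff"},
    scanned_ids=set(predicted) | {"p6", "p8"},
)
print(missed.to_string(index=False))
print(
    "\nCoverage counts recovered ids; accuracy counts recovered ids whose\n"
    "predicted family corresponds to the reference family (G2-like/GLK is\n"
    "accepted for G2-like via the map, HB-other for HD-ZIP is a confusion)."
)
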