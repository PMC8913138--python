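"""Elicit trapezoidal risk evaluations and average them per patient.

Builds three staff evaluations of one child's mortality risk, parameterizes
each trapezoid into its four indexes, and averages them into the single
subjective risk used downstream.
"""

from picurisk import TrapezoidEvaluation, average_indexes, parameterize

evaluations = [
    # short range [lo, hi] is the most plausible risk; long range is the
    # almost-certain envelope, both in percent
    TrapezoidEvaluation("child-001", 20, 40, 10, 70, rater_role="physician"),
    TrapezoidEvaluation("child-001", 30, 50, 30, 50, rater_role="nurse"),
    TrapezoidEvaluation("child-001", 25, 35, 15, 60, rater_role="nurse"),
]

indexes = [parameterize(e) for e in evaluations]
for e, f in zip(evaluations, indexes):
    print(
        f"{e.rater_role:>9}: short [{e.short_lo:.0f}, {e.short_hi:.0f}] "
        f"long [{e.long_lo:.0f}, {e.long_hi:.0f}] -> "
        f"MID={f.mid:.1f} SPR={f.spr:.1f} SPRL={f.sprl:.1f} SPRR={f.sprr:.1f}"
    )

avg = average_indexes(indexes)
print(
    f"\naveraged subjective risk for child-001: MID={avg.mid:.2f}% "
    f"(SPR={avg.spr:.2f}, SPRL={avg.sprl:.2f}, SPRR={avg.sprr:.2f})"
)
print("MID is the midpoint of the short range: the patient-level risk estimate.")
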