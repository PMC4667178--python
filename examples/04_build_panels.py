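"""Construct unrelated-and-outbred reference panels from inbreeding calls.

Given per-individual estimates and externally supplied relationship
pairs, panel A removes low-quality estimates, one member per first/second
degree pair and avuncular / double-first-cousin offspring; panel B
additionally breaks first-cousin pairs and removes first-cousin offspring
(so panel B is always a subset of panel A).
"""

from autozyg import build_panels
from autozyg.pipeline import InbreedingEstimate


def est(iid, best="OUT", lowq=False):
    return InbreedingEstimate(
        id=iid, population="P", f_median=0.01, q_score=5 if lowq else 90,
        lrt_p=0.5, posteriors={}, best_type=best, inbred=best != "OUT",
        low_quality=lowq,
    )


estimates = [
    est("NA001"), est("NA002"), est("NA003"), est("NA004"),
    est("NA005", best="AV"), est("NA006", best="1C"),
    est("NA007"), est("NA008", lowq=True),
]
close_pairs = [("NA001", "NA002")]          # e.g. a parent-offspring pair
cousin_pairs = [("NA003", "NA007")]          # a first-cousin pair

panel_a, panel_b = build_panels(estimates, close_pairs, cousin_pairs)
print("panel A (unrelated to 2nd degree, no AV/2x1C offspring):", panel_a)
print("panel B (unrelated to 1st cousins,  no 1C-or-closer):   ", panel_b)
print(
    "\nNA008 is dropped from both (low Q-score); one member of each pair "
    "is dropped (highest pair count, ties by id); NA005 leaves panel A, "
    "NA006 additionally leaves panel B; panel B is a subset of panel A."
)
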