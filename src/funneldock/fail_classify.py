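"""Three-way classification of docking failures.

A failed target (no funnel in the standard run) is diagnosed by comparing
the standard decoy set against two control refinements started from the
native complex: one with the unbound backbones superposed on the complex
(``unbound_refine``) and one refining the bound conformers themselves
(``bound_refine``).

* **RB sampling failure** — refinement of the unbound conformers finds
  near-native decoys at lower interface energy than anything the standard
  run reached: rigid-body space was simply undersampled.
* **BB sampling failure** — only refinement of the *bound* backbones finds
  such low-energy near-natives: binding-induced backbone change puts the
  native minimum out of reach of rigid-body docking.
* **discrimination failure** — even the bound-backbone refinement cannot
  beat the standard run's energies: the score function does not rank the
  native basin best.

"Lower energy" is formalized with a configurable margin (default 1.0
score units) guarding against float noise; the comparison baseline is the
standard run's overall minimum interface energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf

import pandas as pd

from .capri_metrics import NEAR_NATIVE_IRMSD
from .decoy_eval import COMPLEX_TYPES, DIFFICULTIES, DecoySet, compute_n5, rank_by_interface_energy

__all__ = [
    "FAILURE_LABELS",
    "RefinementComparison",
    "classify_failure",
    "compare_refinements",
    "tabulate_failures",
]

FAILURE_LABELS = ("RB sampling", "BB sampling", "discrimination")


@dataclass(frozen=True)
class RefinementComparison:
    """Energy minima feeding the failure-classification cascade."""

    e_std_min: float
    e_ub_nn: float | None  # min I_sc over near-native unbound-refine decoys
    e_b_nn: float | None  # min I_sc over near-native bound-refine decoys
    margin: float = 1.0


def _near_native_min(ds: DecoySet, top_n: int | None) -> float | None:
    records = rank_by_interface_energy(ds)
    if top_n is not None:
        records = records[:top_n]
    energies = [r.i_sc for r in records if r.irmsd <= NEAR_NATIVE_IRMSD]
    return min(energies) if energies else None


def compare_refinements(std: DecoySet, ub: DecoySet, bd: DecoySet,
                        margin: float = 1.0, top_n: int | None = None) -> RefinementComparison:
    """Collect the minima the cascade needs. ``top_n`` optionally restricts
    each refinement set to its n lowest-energy decoys before the
    near-native minimum is taken (scatter-plot convention uses 10)."""
    if ub.provenance != "unbound_refine":
        raise ValueError(f"ub set has provenance {ub.provenance!r}, expected 'unbound_refine'")
    if bd.provenance != "bound_refine":
        raise ValueError(f"bd set has provenance {bd.provenance!r}, expected 'bound_refine'")
    return RefinementComparison(
        e_std_min=min(r.i_sc for r in std.records),
        e_ub_nn=_near_native_min(ub, top_n),
        e_b_nn=_near_native_min(bd, top_n),
        margin=margin,
    )


def classify_comparison(cmp: RefinementComparison) -> str:
    """Decision cascade over the energy minima; total and deterministic."""
    e_ub = cmp.e_ub_nn if cmp.e_ub_nn is not None else inf
    e_b = cmp.e_b_nn if cmp.e_b_nn is not None else inf
    if e_ub + cmp.margin < cmp.e_std_min:
        return "RB sampling"
    if e_b + cmp.margin < min(e_ub, cmp.e_std_min):
        return "BB sampling"
    return "discrimination"


def classify_failure(std: DecoySet, ub: DecoySet, bd: DecoySet,
                     margin: float = 1.0, top_n: int | None = None) -> str:
    """Label a failed target as RB sampling, BB sampling, or discrimination.

    ``std`` must actually have failed the funnel criterion (N5 < 3).
    """
    if compute_n5(std).success:
        raise ValueError("standard run is a success; failure classification does not apply")
    return classify_comparison(compare_refinements(std, ub, bd, margin=margin, top_n=top_n))


def tabulate_failures(labeled) -> pd.DataFrame:
    """Counts and percentages of failure labels per category.

    Parameters
    ----------
    labeled : iterable of (target_id, complex_type, difficulty, label)

    Returns a DataFrame indexed by category (overall + complex types +
    difficulties) with one count column and one percent column per label.
    """
    labeled = list(labeled)
    if not labeled:
        raise ValueError("no failures to tabulate")
    rows = []
    for target_id, ctype, diff, label in labeled:
        if label not in FAILURE_LABELS:
            raise ValueError(f"{target_id}: unknown failure label {label!r}")
        rows.append((target_id, ctype, diff, label))
    df = pd.DataFrame(rows, columns=["target_id", "complex_type", "difficulty", "label"])

    out = []
    categories = [("overall", None)]
    categories += [(c, ("complex_type", c)) for c in COMPLEX_TYPES]
    categories += [(d, ("difficulty", d)) for d in DIFFICULTIES]
    for name, sel in categories:
        sub = df if sel is None else df[df[sel[0]] == sel[1]]
        row: dict = {"category": name, "n_failures": len(sub)}
        for label in FAILURE_LABELS:
            cnt = int((sub.label == label).sum())
            row[label] = cnt
            row[f"{label} %"] = round(100.0 * cnt / len(sub)) if len(sub) else 0
        out.append(row)
    return pd.DataFrame(out).set_index("category")
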