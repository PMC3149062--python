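"""Decoy-set bookkeeping: score-file I/O, ranking, N5 and funnel calls,
and benchmark-style aggregation.

The file dialect is the Rosetta score-file convention: a whitespace-
delimited table whose header names at least ``I_sc``, ``Irms`` and
``description``; common extras are ``total_score``, ``rms`` (Lrmsd) and
``Fnat``. A docking run is a *success* when at least three of its five
lowest-interface-energy decoys are near-native (N5 >= 3).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .capri_metrics import NEAR_NATIVE_IRMSD, classify_quality

__all__ = [
    "DecoyRecord",
    "DecoySet",
    "FunnelResult",
    "read_scorefile",
    "write_scorefile",
    "rank_by_interface_energy",
    "compute_n5",
    "aggregate_benchmark",
    "load_benchmark_table",
    "PUBLISHED_CATEGORY_SIZES",
    "COMPLEX_TYPES",
    "DIFFICULTIES",
    "PROVENANCES",
]

COMPLEX_TYPES = ("enzyme-inhibitor", "antibody-antigen", "other")
DIFFICULTIES = ("rigid-body", "medium", "difficult")
PROVENANCES = ("standard", "unbound_refine", "bound_refine")

#: Benchmark category sizes as published (used as denominators when
#: aggregating the packaged results table, whose row count differs from the
#: published totals by one target).
PUBLISHED_CATEGORY_SIZES = {
    "overall": 116,
    "rigid-body": 84,
    "medium": 17,
    "difficult": 14,
    "enzyme-inhibitor": 33,
    "antibody-antigen": 23,
    "other": 60,
}


@dataclass
class DecoyRecord:
    """Scores and accuracy measures for one decoy."""

    description: str
    i_sc: float
    irmsd: float
    total_score: float | None = None
    lrmsd: float | None = None
    fnat: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not pd.notna(self.i_sc):
            raise ValueError(f"decoy {self.description!r}: I_sc must be finite")
        if self.irmsd < 0:
            raise ValueError(f"decoy {self.description!r}: Irms must be >= 0")


@dataclass
class DecoySet:
    """An ordered decoy collection with provenance and benchmark labels."""

    records: list[DecoyRecord]
    provenance: str = "standard"
    target_id: str = ""
    complex_type: str | None = None
    difficulty: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a DecoySet needs at least one record")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        names = [r.description for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("decoy descriptions must be unique")
        if self.complex_type is not None and self.complex_type not in COMPLEX_TYPES:
            raise ValueError(f"unknown complex type {self.complex_type!r}")
        if self.difficulty is not None and self.difficulty not in DIFFICULTIES:
            raise ValueError(f"unknown difficulty {self.difficulty!r}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class FunnelResult:
    """Funnel call for one decoy set: N5, success (N5 >= 3), and the
    quality class of the closest decoy among the five best scorers."""

    n5: int
    success: bool
    best_irmsd_top5: float
    quality: str


_COLUMN_MAP = {
    "description": "description",
    "I_sc": "i_sc",
    "Irms": "irmsd",
    "total_score": "total_score",
    "rms": "lrmsd",
    "Fnat": "fnat",
}


def read_scorefile(path, **set_kwargs) -> DecoySet:
    """Read a whitespace score file into a DecoySet.

    Lines may carry a leading ``SCORE:`` tag (stripped). Mandatory columns:
    ``I_sc``, ``Irms``, ``description``. Unknown columns are preserved in
    each record's ``extras``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if toks and toks[0] == "SCORE:":
                toks = toks[1:]
            if toks:
                rows.append(toks)
    if not rows:
        raise ValueError(f"{path}: empty score file")
    header, data = rows[0], rows[1:]
    for col in ("I_sc", "Irms", "description"):
        if col not in header:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    records = []
    for i, toks in enumerate(data, start=2):
        if len(toks) != len(header):
            raise ValueError(f"{path}: row {i} has {len(toks)} fields, expected {len(header)}")
        raw = dict(zip(header, toks))
        kw: dict = {"extras": {}}
        for col, val in raw.items():
            key = _COLUMN_MAP.get(col)
            if key == "description":
                kw[key] = val
            elif key is not None:
                if val == "NA" and col not in ("I_sc", "Irms"):
                    continue  # optional column left blank on write
                try:
                    kw[key] = float(val)
                except ValueError as exc:
                    raise ValueError(f"{path}: row {i}: non-numeric {col}={val!r}") from exc
            else:
                kw["extras"][col] = val
        records.append(DecoyRecord(**kw))
    return DecoySet(records, **set_kwargs)


def write_scorefile(ds: DecoySet, path) -> None:
    """Write a DecoySet as a whitespace score table (Rosetta dialect)."""
    cols = ["total_score", "I_sc", "rms", "Irms", "Fnat", "description"]
    attrs = ["total_score", "i_sc", "lrmsd", "irmsd", "fnat", "description"]
    with open(path, "w") as fh:
        fh.write(" ".join(f"{c:>12s}" for c in cols) + "\n")
        for r in ds.records:
            vals = []
            for a in attrs:
                v = getattr(r, a)
                if a == "description":
                    vals.append(f"{v:>12s}")
                elif v is None:
                    vals.append(f"{'NA':>12s}")
                else:
                    vals.append(f"{v:12.3f}")
            fh.write(" ".join(vals) + "\n")


def rank_by_interface_energy(ds: DecoySet) -> list[DecoyRecord]:
    """Records sorted ascending by interface energy; ties broken by
    description so the ordering is deterministic."""
    return sorted(ds.records, key=lambda r: (r.i_sc, r.description))


def compute_n5(ds: DecoySet) -> FunnelResult:
    """Count near-native decoys among the five lowest-interface-energy
    decoys and call the funnel (success iff N5 >= 3)."""
    if len(ds) < 5:
        raise ValueError(f"need >= 5 decoys to compute N5, got {len(ds)}")
    top5 = rank_by_interface_energy(ds)[:5]
    n5 = sum(1 for r in top5 if r.irmsd <= NEAR_NATIVE_IRMSD)
    best = min(r.irmsd for r in top5)
    return FunnelResult(n5=n5, success=n5 >= 3, best_irmsd_top5=best,
                        quality=classify_quality(best))


def aggregate_benchmark(results, denominators: dict | None = None) -> pd.DataFrame:
    """Summarize funnel outcomes by complex type and difficulty.

    Parameters
    ----------
    results : iterable of (target_id, complex_type, difficulty, FunnelResult)
    denominators : optional mapping category -> published target count; when
        given, percentages use these instead of the observed row counts
        (the packaged results table is one row short of the published
        benchmark size).

    Returns a DataFrame indexed by category with columns ``n``,
    ``successes`` and ``success_pct`` (rounded to the nearest integer
    percent), including an ``overall`` row.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to aggregate")
    rows = []
    for target_id, ctype, diff, fr in results:
        if ctype not in COMPLEX_TYPES:
            raise ValueError(f"{target_id}: unknown complex type {ctype!r}")
        if diff not in DIFFICULTIES:
            raise ValueError(f"{target_id}: unknown difficulty {diff!r}")
        rows.append((target_id, ctype, diff, bool(fr.success)))
    df = pd.DataFrame(rows, columns=["target_id", "complex_type", "difficulty", "success"])

    out = []
    categories = [("overall", slice(None))]
    categories += [(c, df.complex_type == c) for c in COMPLEX_TYPES]
    categories += [(d, df.difficulty == d) for d in DIFFICULTIES]
    for name, mask in categories:
        sub = df if name == "overall" else df[mask]
        n = len(sub)
        denom = (denominators or {}).get(name, n)
        succ = int(sub.success.sum())
        pct = round(100.0 * succ / denom) if denom else 0
        out.append({"category": name, "n": denom, "successes": succ, "success_pct": pct})
    return pd.DataFrame(out).set_index("category")


def load_benchmark_table() -> pd.DataFrame:
    """Load the packaged transcription of the published RosettaDock v3.2
    benchmark summary tables (per-target N5, bootstrap statistics, best
    interface RMSD, quality stars for successes, failure labels for
    failures). See the CSV header for provenance notes."""
    ref = importlib.resources.files("funneldock") / "data" / "benchmark_v32.csv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")
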