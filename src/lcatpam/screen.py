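"""Virtual-screen triage of compound libraries.

Reproduces the staged filtering applied before docking-based shortlisting of
LCAT membrane-binding-domain ligands:

1. charge filter — any compound carrying a charged group at the prepared
   protonation state is removed (the one charged reference compound failed to
   bind in vitro);
2. molecular-mass window — below 100 g/mol or above 600 g/mol removed
   (bounds inclusive-pass: exactly 100 or 600 survives);
3. docking-score cut-off — standard-precision (SP) score must reach −7.0
   (more negative = better predicted binding; score ≤ cutoff passes).

Survivors are re-docked at extra precision (XP) and shortlisted for MD by
best XP score, at most one per scaffold/diversity group — a deterministic
surrogate for manual scaffold-diversity picking.

Charge assignment from structure is out of scope; records carry a
precomputed ``has_charged_group`` boolean.  Masses may be given directly or
computed from a Hill-notation formula with IUPAC standard atomic weights.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum

import pandas as pd
from rdkit import Chem

__all__ = [
    "Status",
    "CompoundRecord",
    "ScreenReport",
    "mass_from_formula",
    "apply_filters",
    "shortlist_md_candidates",
    "read_library",
]


class Status(str, Enum):
    PENDING = "pending"
    REJECTED_CHARGE = "rejected_charge"
    REJECTED_MASS = "rejected_mass"
    REJECTED_SCORE = "rejected_score"
    MD_CANDIDATE = "md_candidate"


@dataclass
class CompoundRecord:
    """One screening-library entry."""

    compound_id: str
    name: str = ""
    formula: str | None = None
    mass: float | None = None
    has_charged_group: bool = False
    docking_score_sp: float | None = None
    docking_score_xp: float | None = None
    diversity_key: str | None = None
    status: Status = Status.PENDING

    def __post_init__(self) -> None:
        if self.mass is not None and self.mass <= 0:
            raise ValueError(f"{self.compound_id}: mass must be > 0")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_PERIODIC_TABLE = Chem.GetPeriodicTable()


def mass_from_formula(formula: str) -> float:
    """Molecular mass in g/mol from a Hill-notation formula.

    Uses standard atomic weights, e.g. ``"H2O"`` → 18.015,
    ``"C12H22O11"`` → 342.30.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    formula = formula.strip()
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"malformed formula {formula!r} at position {pos}: "
                f"{formula[pos:match.start()]!r}"
            )
        symbol, count = match.group(1), match.group(2)
        try:
            weight = _PERIODIC_TABLE.GetAtomicWeight(symbol)
        except Exception:
            weight = 0.0
        if weight <= 0:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        total += weight * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}: trailing {formula[pos:]!r}")
    return total


@dataclass
class ScreenReport:
    """Stage counts and per-compound statuses of one triage run."""

    records: list[CompoundRecord]
    counts: dict[str, int]
    mass_min: float
    mass_max: float
    score_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "name": [r.name for r in self.records],
                "mass": [r.mass for r in self.records],
                "has_charged_group": [r.has_charged_group for r in self.records],
                "docking_score_sp": [r.docking_score_sp for r in self.records],
                "docking_score_xp": [r.docking_score_xp for r in self.records],
                "status": [r.status.value for r in self.records],
            }
        )

    def counts_json(self) -> str:
        return json.dumps(self.counts, indent=2)

    @property
    def md_candidates(self) -> list[CompoundRecord]:
        return [r for r in self.records if r.status is Status.MD_CANDIDATE]


def apply_filters(
    library: list[CompoundRecord],
    mass_min: float = 100.0,
    mass_max: float = 600.0,
    score_cutoff: float = -7.0,
) -> ScreenReport:
    """Run the staged triage: charge → mass window → SP-score cut-off.

    A compound failing several criteria is labelled by the first filter it
    fails.  Mass bounds pass inclusively (100.0 and 600.0 survive); the score
    stage passes when SP score ≤ cutoff.  A survivor with no SP score stays
    ``pending`` at the score stage; survivors of all three stages become
    ``md_candidate``.  Records are not mutated; a fresh report is returned.
    """
    out: list[CompoundRecord] = []
    n_input = len(library)
    n_after_charge = n_after_mass = n_after_score = n_xp = 0
    for rec in library:
        mass = rec.mass
        if mass is None:
            if rec.formula is None:
                raise ValueError(
                    f"compound {rec.compound_id} has neither mass nor formula"
                )
            mass = mass_from_formula(rec.formula)
        rec = replace(rec, mass=mass)

        if rec.has_charged_group:
            out.append(replace(rec, status=Status.REJECTED_CHARGE))
            continue
        n_after_charge += 1
        if mass < mass_min or mass > mass_max:
            out.append(replace(rec, status=Status.REJECTED_MASS))
            continue
        n_after_mass += 1
        if rec.docking_score_sp is None:
            out.append(replace(rec, status=Status.PENDING))
            continue
        if rec.docking_score_sp > score_cutoff:
            out.append(replace(rec, status=Status.REJECTED_SCORE))
            continue
        n_after_score += 1
        if rec.docking_score_xp is not None:
            n_xp += 1
        out.append(replace(rec, status=Status.MD_CANDIDATE))

    counts = {
        "input": n_input,
        "after_charge": n_after_charge,
        "after_mass": n_after_mass,
        "after_score": n_after_score,
        "xp_docked": n_xp,
        "md_candidates": n_after_score,
    }
    return ScreenReport(
        records=out,
        counts=counts,
        mass_min=mass_min,
        mass_max=mass_max,
        score_cutoff=score_cutoff,
    )


def shortlist_md_candidates(
    report: ScreenReport,
    k: int,
    diversity_key: str | None = "diversity_key",
) -> list[str]:
    """Top-k filter survivors by best (most negative) XP score.

    With a diversity key, at most one compound per group is kept (the
    best-scored; a deterministic surrogate for manual scaffold-diversity
    picking).  Ties break lexicographically on compound id.  Candidates
    without an XP score rank after all scored ones.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    candidates = report.md_candidates
    if not candidates:
        raise ValueError("no compounds passed all filters")

    def sort_key(rec: CompoundRecord):
        score = rec.docking_score_xp
        return (score is None, score if score is not None else 0.0, rec.compound_id)

    ranked = sorted(candidates, key=sort_key)
    if diversity_key is not None:
        seen: set[str] = set()
        kept = []
        for rec in ranked:
            group = getattr(rec, "diversity_key", None)
            if group is None:
                kept.append(rec)
                continue
            if group in seen:
                continue
            seen.add(group)
            kept.append(rec)
        ranked = kept
    return [r.compound_id for r in ranked[:k]]


def read_library(path) -> list[CompoundRecord]:
    """Read a delimited library table into CompoundRecords.

    Expected header columns: compound_id, name, formula, mass,
    has_charged_group, docking_score_sp, docking_score_xp, and optionally
    diversity_key.  Missing optional cells may be blank.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing required column compound_id")

    def opt(row, col):
        if col not in df.columns or pd.isna(row[col]):
            return None
        return row[col]

    records = []
    for _, row in df.iterrows():
        records.append(
            CompoundRecord(
                compound_id=str(row["compound_id"]),
                name=str(opt(row, "name") or ""),
                formula=opt(row, "formula"),
                mass=None if opt(row, "mass") is None else float(row["mass"]),
                has_charged_group=bool(opt(row, "has_charged_group") or False),
                docking_score_sp=None
                if opt(row, "docking_score_sp") is None
                else float(row["docking_score_sp"]),
                docking_score_xp=None
                if opt(row, "docking_score_xp") is None
                else float(row["docking_score_xp"]),
                diversity_key=None
                if opt(row, "diversity_key") is None
                else str(row["diversity_key"]),
            )
        )
    return records
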