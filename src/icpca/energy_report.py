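"""Per-frame energy-table aggregation.

Summarizes a molecular-dynamics energy table into (i) the mean relative
contribution of kinetic vs potential energy to the total and (ii) the
shares of the bonded terms (bond, angle, dihedral) in their sum. A
Urey-Bradley column, if present, is folded into the angle term before
shares are formed (the CHARMM convention); a missing bond column (all
bonds constrained during MD) yields a zero bond share with an explicit
"absent" flag rather than a silent zero.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NumericalError, SchemaError

__all__ = ["EnergyBreakdown", "summarize"]

_BONDED = ("bond", "angle", "dihedral")


@dataclasses.dataclass
class EnergyBreakdown:
    """Mean energy fractions plus the per-frame series behind them."""

    kinetic_fraction: float
    potential_fraction: float
    bonded_shares: dict[str, float]          # bond/angle/dihedral, sum 1
    per_frame: pd.DataFrame                  # per-frame fractions and shares
    urey_bradley_folded: bool
    absent_terms: tuple[str, ...]
    flagged_frames: np.ndarray               # frames with non-positive |K|+|P|

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kinetic_fraction": self.kinetic_fraction,
            "potential_fraction": self.potential_fraction,
            "bonded_shares": self.bonded_shares,
            "urey_bradley_folded": self.urey_bradley_folded,
            "absent_terms": list(self.absent_terms),
            "n_frames": int(len(self.per_frame)),
            "n_flagged_frames": int(self.flagged_frames.size),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        self.per_frame.to_csv(path, sep="\t", index_label="frame",
                              float_format="%.8g")


def summarize(records: pd.DataFrame) -> EnergyBreakdown:
    """Aggregate a per-frame energy table into mean fractions.

    Fractions are computed per frame and then averaged. The kinetic /
    potential split uses |kinetic| + |potential| as the per-frame
    denominator so that near-cancelling totals cannot blow up a frame;
    frames where that denominator is not positive are flagged and
    excluded from the averages (all frames flagged is an error).
    """
    cols = {c.strip().lower() for c in records.columns}
    missing = [c for c in ("kinetic", "potential") if c not in cols]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    df = records.rename(columns=lambda c: str(c).strip().lower())

    kin = df["kinetic"].to_numpy(float)
    pot = df["potential"].to_numpy(float)
    denom = np.abs(kin) + np.abs(pot)
    ok = denom > 0
    flagged = np.flatnonzero(~ok)
    if not ok.any():
        raise NumericalError("every frame has zero |kinetic| + |potential|")

    kin_frac = np.where(ok, np.abs(kin) / np.where(ok, denom, 1.0), np.nan)
    pot_frac = np.where(ok, np.abs(pot) / np.where(ok, denom, 1.0), np.nan)

    per_frame = pd.DataFrame({"kinetic_fraction": kin_frac,
                              "potential_fraction": pot_frac})

    present = [t for t in _BONDED if t in df.columns]
    absent = tuple(t for t in _BONDED if t not in df.columns)
    urey_folded = False
    shares: dict[str, float] = {}
    if present:
        terms = {t: (df[t].to_numpy(float) if t in df.columns
                     else np.zeros(len(df))) for t in _BONDED}
        if "urey_bradley" in df.columns:
            if "angle" not in df.columns:
                raise SchemaError("urey_bradley present without an angle column")
            terms["angle"] = terms["angle"] + df["urey_bradley"].to_numpy(float)
            urey_folded = True
        tot = sum(np.abs(terms[t]) for t in _BONDED)
        good = tot > 0
        for t in _BONDED:
            share = np.where(good, np.abs(terms[t]) / np.where(good, tot, 1.0),
                             np.nan)
            per_frame[f"{t}_share"] = share
            shares[t] = float(np.nanmean(share)) if good.any() else float("nan")

    return EnergyBreakdown(
        kinetic_fraction=float(np.nanmean(kin_frac)),
        potential_fraction=float(np.nanmean(pot_frac)),
        bonded_shares=shares,
        per_frame=per_frame,
        urey_bradley_folded=urey_folded,
        absent_terms=absent,
        flagged_frames=flagged,
    )
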