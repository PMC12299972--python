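"""Blank-corrected substrate utilization and functional diversity indices.

For each time point the three replicate blocks are blank-corrected against
their own water-control well and then averaged, giving one utilization value
n_i per substrate (i = 1..31).  On that vector the module computes

* AWCD  = sum(n_i) / 31                (average well color development)
* H     = -sum(p_i ln p_i)             (Shannon, nats), p_i = n_i / sum(n_i)
* D     = 1 - sum(p_i^2)               (Simpson)
* U     = sum(n_i^2)                   (McIntosh as printed; ``sqrt`` form
                                        gives the conventional Euclidean norm)

Negative C_i - R_i differences are floored at zero by default before any
index is computed; the unfloored differences are preserved on the profile.
An all-zero profile yields missing H and D (with a warning), never 0, so
"no activity" stays distinguishable from "one dominant substrate".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError
from .plate_io import GUILDS, PlateLayout, PlateTimeSeries

N_SUBSTRATES = 31


@dataclass
class CorrectedProfile:
    """Replicate-averaged, blank-corrected utilization at one time point."""

    sample_id: str
    treatment: str
    time: float
    substrates: list[str]
    guilds: np.ndarray
    ni: np.ndarray  # floored at 0 under the default policy
    raw_diff: np.ndarray  # unfloored Ci - Ri block means

    def __post_init__(self) -> None:
        self.ni = np.asarray(self.ni, dtype=float)
        self.raw_diff = np.asarray(self.raw_diff, dtype=float)
        if len(self.substrates) != N_SUBSTRATES or self.ni.shape != (N_SUBSTRATES,):
            raise ValidationError(
                f"profile must have exactly {N_SUBSTRATES} substrates, "
                f"got {len(self.substrates)}"
            )


def blank_correct(
    ts: PlateTimeSeries,
    layout: PlateLayout,
    floor_at_zero: bool = True,
) -> list[CorrectedProfile]:
    """Per time point: average the three block replicates of Ci - Ri.

    Ri is the reading of each block's own water-control well, so correction
    happens within blocks before averaging across them.  A time point whose
    control well is missing in any block is skipped with a warning; a
    substrate missing in all three blocks is an error.
    """
    substrates = layout.substrates
    guilds = np.array([layout.guild_of(s) for s in substrates])
    well_row = {w: i for i, w in enumerate(ts.od.index)}
    ctrl_idx = np.array([well_row[layout.control_well(b)] for b in (1, 2, 3)])
    sub_idx = np.array(
        [
            [well_row[layout.substrate_wells(s)[b]] for b in (1, 2, 3)]
            for s in substrates
        ]
    )
    vals = ts.od.to_numpy(dtype=float)

    profiles: list[CorrectedProfile] = []
    for j, t in enumerate(ts.od.columns):
        col = vals[:, j]
        ri = col[ctrl_idx]
        if np.isnan(ri).any():
            warnings.warn(
                f"plate {ts.sample_id}: skipping t={t} h (missing control well)",
                stacklevel=2,
            )
            continue
        diffs = col[sub_idx] - ri[None, :]  # 31 substrates x 3 blocks
        present = ~np.isnan(diffs)
        if not present.any(axis=1).all():
            s = substrates[int(np.flatnonzero(~present.any(axis=1))[0])]
            raise ValidationError(
                f"plate {ts.sample_id}: substrate {s!r} missing in all blocks "
                f"at t={t} h"
            )
        raw = np.nanmean(diffs, axis=1)
        ni = np.maximum(raw, 0.0) if floor_at_zero else raw.copy()
        profiles.append(
            CorrectedProfile(
                sample_id=ts.sample_id,
                treatment=ts.treatment,
                time=float(t),
                substrates=substrates,
                guilds=guilds,
                ni=ni,
                raw_diff=raw,
            )
        )
    return profiles


def awcd(profile: CorrectedProfile, use_floored: bool = True) -> float:
    """Average well color development: sum of utilization over the 31 wells."""
    vals = profile.ni if use_floored else profile.raw_diff
    return float(np.sum(vals) / N_SUBSTRATES)


def _proportions(profile: CorrectedProfile) -> np.ndarray | None:
    total = float(np.sum(profile.ni))
    if total <= 0.0:
        warnings.warn(
            f"plate {profile.sample_id}, t={profile.time}: total utilization is 0; "
            "Shannon/Simpson undefined",
            stacklevel=3,
        )
        return None
    return profile.ni / total


def shannon_index(profile: CorrectedProfile) -> float:
    """H = -sum p_i ln p_i in nats, with 0 ln 0 := 0; NaN if no activity."""
    p = _proportions(profile)
    if p is None:
        return math.nan
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def simpson_index(profile: CorrectedProfile) -> float:
    """D = 1 - sum p_i^2; NaN if no activity."""
    p = _proportions(profile)
    if p is None:
        return math.nan
    return float(1.0 - np.sum(p**2))


def mcintosh_index(profile: CorrectedProfile, form: str = "paper") -> float:
    """McIntosh U: ``paper`` form sum n_i^2, ``sqrt`` form its square root."""
    ss = float(np.sum(profile.ni**2))
    if form == "paper":
        return ss
    if form == "sqrt":
        return math.sqrt(ss)
    raise ValidationError(f"unknown McIntosh form {form!r}, expected 'paper' or 'sqrt'")


def diversity_trajectory(
    ts: PlateTimeSeries,
    layout: PlateLayout,
    mcintosh_form: str = "paper",
    floor_at_zero: bool = True,
) -> pd.DataFrame:
    """All four indices at every usable time point, in time order.

    Columns: sample_id, treatment, time_h, awcd, shannon, simpson, mcintosh,
    mcintosh_form.
    """
    profiles = blank_correct(ts, layout, floor_at_zero=floor_at_zero)
    if not profiles:
        raise DegenerateDataError(
            f"plate {ts.sample_id}: no usable time points after control-well checks"
        )
    rows = []
    for p in profiles:
        rows.append(
            {
                "sample_id": p.sample_id,
                "treatment": p.treatment,
                "time_h": p.time,
                "awcd": awcd(p),
                "shannon": shannon_index(p),
                "simpson": simpson_index(p),
                "mcintosh": mcintosh_index(p, form=mcintosh_form),
                "mcintosh_form": mcintosh_form,
            }
        )
    return pd.DataFrame(rows)


def guild_profile(profile: CorrectedProfile, layout: PlateLayout) -> pd.DataFrame:
    """Mean and sum of n_i per substrate guild.

    The six guilds partition the 31 substrates, so the guild sums add up to
    the profile total.
    """
    df = pd.DataFrame(
        {"guild": profile.guilds, "ni": profile.ni, "substrate": profile.substrates}
    )
    agg = (
        df.groupby("guild", sort=False)
        .agg(mean_ni=("ni", "mean"), sum_ni=("ni", "sum"), n_substrates=("ni", "size"))
        .reindex(GUILDS)
        .reset_index()
    )
    agg.insert(0, "time_h", profile.time)
    agg.insert(0, "treatment", profile.treatment)
    agg.insert(0, "sample_id", profile.sample_id)
    return agg


def substrate_heatmap_matrix(
    plates: list[PlateTimeSeries],
    layout: PlateLayout,
    statistic: str = "cumulative",
) -> pd.DataFrame:
    """Replicate-mean utilization per substrate and time, per treatment.

    ``statistic='cumulative'`` reports the blank-corrected n_i at each time;
    ``'rate'`` reports its per-hour forward difference.  Tidy output columns:
    treatment, guild, substrate, time_h, value — 31 substrates x T times per
    treatment, rows ordered by guild then substrate name.
    """
    if statistic not in ("cumulative", "rate"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    recs = []
    for ts in plates:
        for p in blank_correct(ts, layout):
            for s, g, v in zip(p.substrates, p.guilds, p.ni):
                recs.append(
                    {
                        "treatment": p.treatment,
                        "guild": g,
                        "substrate": s,
                        "time_h": p.time,
                        "sample_id": p.sample_id,
                        "ni": v,
                    }
                )
    if not recs:
        raise DegenerateDataError("no usable profiles for heatmap matrix")
    df = pd.DataFrame(recs)
    mean = (
        df.groupby(["treatment", "guild", "substrate", "time_h"], sort=False)["ni"]
        .mean()
        .reset_index(name="value")
    )
    if statistic == "rate":
        mean = mean.sort_values(["treatment", "substrate", "time_h"], kind="stable")
        grp = mean.groupby(["treatment", "substrate"], sort=False)
        mean["value"] = grp["value"].diff() / grp["time_h"].diff()
        mean = mean.dropna(subset=["value"]).copy()
    order = {g: i for i, g in enumerate(GUILDS)}
    mean["_g"] = mean["guild"].map(order)
    mean = (
        mean.sort_values(["treatment", "_g", "substrate", "time_h"], kind="stable")
        .drop(columns="_g")
        .reset_index(drop=True)
    )
    return mean
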