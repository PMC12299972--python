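"""Reading, validation and writing of EcoPlate layouts and OD590 time series.

The structural model is the 96-well Biolog EcoPlate: three replicate blocks
(column ranges 1-4, 5-8, 9-12), each holding the same 31 carbon substrates
plus one water-control well (A1, A5, A9 in the default layout).  All file
interfaces are plain UTF-8 CSV with a header row and "." decimals, so that
write -> read round trips are bit-exact on the decimal strings.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

from .errors import LayoutError, ValidationError

ROWS = "ABCDEFGH"
N_COLS = 12

#: Guilds of the 31 EcoPlate substrates plus the water control.
GUILDS = (
    "carbohydrate",
    "amino_acid",
    "organic_acid",
    "polymer",
    "phenolic",
    "amine",
)
CONTROL = "CONTROL"

# One replicate block of the standard commercial EcoPlate, in column-major
# well order (A,B,...,H down each of the four block columns).  The same
# pattern repeats in columns 1-4, 5-8 and 9-12.
_BLOCK_PATTERN: list[tuple[str, str]] = [
    ("Water", "control"),
    ("Pyruvic acid methyl ester", "carbohydrate"),
    ("Tween 40", "polymer"),
    ("Tween 80", "polymer"),
    ("alpha-Cyclodextrin", "polymer"),
    ("Glycogen", "polymer"),
    ("D-Cellobiose", "carbohydrate"),
    ("alpha-D-Lactose", "carbohydrate"),
    ("beta-Methyl-D-glucoside", "carbohydrate"),
    ("D-Xylose", "carbohydrate"),
    ("i-Erythritol", "carbohydrate"),
    ("D-Mannitol", "carbohydrate"),
    ("N-Acetyl-D-glucosamine", "carbohydrate"),
    ("D-Glucosaminic acid", "organic_acid"),
    ("Glucose-1-phosphate", "carbohydrate"),
    ("D,L-alpha-Glycerol phosphate", "carbohydrate"),
    ("D-Galactonic acid gamma-lactone", "organic_acid"),
    ("D-Galacturonic acid", "organic_acid"),
    ("2-Hydroxybenzoic acid", "phenolic"),
    ("4-Hydroxybenzoic acid", "phenolic"),
    ("gamma-Hydroxybutyric acid", "organic_acid"),
    ("Itaconic acid", "organic_acid"),
    ("alpha-Ketobutyric acid", "organic_acid"),
    ("D-Malic acid", "organic_acid"),
    ("L-Arginine", "amino_acid"),
    ("L-Asparagine", "amino_acid"),
    ("L-Phenylalanine", "amino_acid"),
    ("L-Serine", "amino_acid"),
    ("L-Threonine", "amino_acid"),
    ("Glycyl-L-glutamic acid", "amino_acid"),
    ("Phenylethylamine", "amine"),
    ("Putrescine", "amine"),
]


def all_well_ids() -> list[str]:
    """The 96 well IDs in row-major order A1..A12, B1..H12."""
    return [f"{r}{c}" for r in ROWS for c in range(1, N_COLS + 1)]


@dataclass(frozen=True)
class PlateLayout:
    """Validated mapping of the 96 wells to substrates, guilds and blocks.

    ``table`` has one row per well with columns ``well_id``, ``substrate``
    (or ``CONTROL``), ``guild`` and ``block`` (1..3).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_layout(self.table)

    @cached_property
    def substrates(self) -> list[str]:
        """The 31 substrate names, ordered by guild then name."""
        sub = self.table[self.table["substrate"] != CONTROL]
        first = sub.drop_duplicates("substrate").copy()
        order = {g: i for i, g in enumerate(GUILDS)}
        first["_g"] = first["guild"].map(order)
        first = first.sort_values(["_g", "substrate"])
        return first["substrate"].tolist()

    @cached_property
    def _guilds(self) -> dict[str, str]:
        sub = self.table[self.table["substrate"] != CONTROL]
        return dict(zip(sub["substrate"], sub["guild"]))

    @cached_property
    def _wells(self) -> dict[str, dict[int, str]]:
        out: dict[str, dict[int, str]] = {}
        for r in self.table.itertuples():
            out.setdefault(r.substrate, {})[r.block] = r.well_id
        return out

    def guild_of(self, substrate: str) -> str:
        return self._guilds[substrate]

    def control_well(self, block: int) -> str:
        return self._wells[CONTROL][block]

    def substrate_wells(self, substrate: str) -> dict[int, str]:
        """Block -> well_id for one substrate."""
        return self._wells[substrate]


def _validate_layout(table: pd.DataFrame) -> None:
    required = {"well_id", "substrate", "guild", "block"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise LayoutError(f"layout missing columns: {sorted(missing_cols)}")

    wells = list(table["well_id"])
    expected = set(all_well_ids())
    got = set(wells)
    if len(wells) != len(got):
        dup = sorted({w for w in wells if wells.count(w) > 1})
        raise LayoutError(f"duplicate well IDs in layout: {dup}")
    if got != expected:
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        parts = []
        if missing:
            parts.append(f"missing wells {missing}")
        if extra:
            parts.append(f"unknown wells {extra}")
        raise LayoutError("layout is not a full 96-well plate: " + "; ".join(parts))

    bad_guild = table[~table["guild"].isin(GUILDS + ("control",))]
    if not bad_guild.empty:
        w = bad_guild["well_id"].iloc[0]
        g = bad_guild["guild"].iloc[0]
        raise LayoutError(f"unknown guild {g!r} at well {w}")

    blocks = sorted(table["block"].unique())
    if blocks != [1, 2, 3]:
        raise LayoutError(f"expected replicate blocks 1..3, found {blocks}")

    mismatch = table[
        (table["substrate"] == CONTROL) ^ (table["guild"] == "control")
    ]
    if not mismatch.empty:
        raise LayoutError(
            f"control guild/substrate mismatch at well {mismatch['well_id'].iloc[0]}"
        )

    per_block_sets: dict[int, set[str]] = {}
    for b, grp in table.groupby("block"):
        subs = grp[grp["substrate"] != CONTROL]["substrate"]
        n_ctrl = int((grp["substrate"] == CONTROL).sum())
        if n_ctrl != 1:
            raise LayoutError(f"block {b} has {n_ctrl} control wells, expected 1")
        if subs.duplicated().any():
            dup = subs[subs.duplicated()].iloc[0]
            well = grp[grp["substrate"] == dup]["well_id"].iloc[-1]
            raise LayoutError(
                f"substrate {dup!r} duplicated within block {b} (well {well})"
            )
        if len(subs) != 31:
            raise LayoutError(f"block {b} has {len(subs)} substrate wells, expected 31")
        per_block_sets[b] = set(subs)

    union = set().union(*per_block_sets.values())
    for s in sorted(union):
        present = [b for b in (1, 2, 3) if s in per_block_sets[b]]
        if len(present) != 3:
            raise LayoutError(
                f"substrate {s!r} present only in blocks {present}, expected all 3"
            )
        guilds = set(table[table["substrate"] == s]["guild"])
        if len(guilds) != 1:
            raise LayoutError(f"substrate {s!r} has conflicting guilds {sorted(guilds)}")


def default_eco_layout() -> PlateLayout:
    """The standard EcoPlate layout: blocks in columns 1-4, 5-8, 9-12."""
    records = []
    for block in (1, 2, 3):
        col0 = 4 * (block - 1)
        for i, (substrate, guild) in enumerate(_BLOCK_PATTERN):
            row = ROWS[i % 8]
            col = col0 + i // 8 + 1
            records.append(
                {
                    "well_id": f"{row}{col}",
                    "substrate": CONTROL if guild == "control" else substrate,
                    "guild": guild,
                    "block": block,
                }
            )
    table = pd.DataFrame.from_records(records)
    # reorder row-major to match well ID convention
    order = {w: i for i, w in enumerate(all_well_ids())}
    table = table.sort_values("well_id", key=lambda s: s.map(order)).reset_index(drop=True)
    return PlateLayout(table)


def read_layout(path: str | None = None) -> PlateLayout:
    """Read a layout CSV (well_id, substrate, guild, block); default EcoPlate if omitted."""
    if path is None:
        return default_eco_layout()
    table = pd.read_csv(path, dtype={"well_id": str, "substrate": str, "guild": str})
    if "block" in table.columns:
        table["block"] = table["block"].astype(int)
    return PlateLayout(table)


def write_layout(layout: PlateLayout, path: str) -> None:
    layout.table.to_csv(path, index=False)


@dataclass
class PlateTimeSeries:
    """OD590 readings for one plate (one pot's soil suspension).

    ``od`` is a 96 x T frame indexed by well ID with time-point columns in
    hours; missing readings are NaN and are never imputed here.
    """

    sample_id: str
    treatment: str
    od: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.od.columns, dtype=float)

    def __post_init__(self) -> None:
        times = np.asarray(self.od.columns, dtype=float)
        if len(times) == 0:
            raise ValidationError(f"plate {self.sample_id}: no time points")
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"plate {self.sample_id}: time points must be non-negative and "
                f"strictly increasing, got {times.tolist()}"
            )
        vals = self.od.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] < 0):
            bad = np.argwhere((vals < 0) & np.isfinite(vals))[0]
            raise ValidationError(
                f"plate {self.sample_id}: negative OD at well "
                f"{self.od.index[bad[0]]}, t={self.od.columns[bad[1]]}"
            )

    @property
    def n_readings(self) -> int:
        return int(self.od.notna().sum().sum())


def _assemble_plate(
    sample_id: str,
    treatment: str,
    rows: pd.DataFrame,
    allow_missing: bool,
) -> PlateTimeSeries:
    dup = rows.duplicated(subset=["well_id", "time_h"])
    if dup.any():
        r = rows[dup].iloc[0]
        raise ValidationError(
            f"plate {sample_id}: duplicate reading for well {r['well_id']} "
            f"at t={r['time_h']}"
        )
    wide = rows.pivot(index="well_id", columns="time_h", values="od590")
    wide = wide.reindex(all_well_ids())
    wide = wide[sorted(wide.columns)]
    if wide.isna().any().any() and not allow_missing:
        missing = [
            (w, t)
            for w in wide.index
            for t in wide.columns
            if pd.isna(wide.at[w, t])
        ]
        raise ValidationError(
            f"plate {sample_id}: {len(missing)} missing (well, time) cells, "
            f"first {missing[0]}; pass allow_missing=True to carry them as NaN"
        )
    return PlateTimeSeries(sample_id=sample_id, treatment=treatment, od=wide)


def read_plates(
    path: str | io.TextIOBase,
    dialect: str = "long",
    allow_missing: bool = False,
) -> list[PlateTimeSeries]:
    """Read every plate in a long- or wide-dialect OD590 CSV.

    Long dialect columns: sample_id, treatment, time_h, well_id, od590.
    Wide dialect columns: sample_id, treatment, time_h, row, c1..c12 —
    one 8x12 grid per (sample, time), eight rows A..H.
    """
    if dialect == "long":
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "treatment": str, "well_id": str},
            float_precision="round_trip",
        )
        required = {"sample_id", "treatment", "time_h", "well_id", "od590"}
    elif dialect == "wide":
        df = pd.read_csv(
            path,
            dtype={"sample_id": str, "treatment": str, "row": str},
            float_precision="round_trip",
        )
        required = {"sample_id", "treatment", "time_h", "row"} | {
            f"c{c}" for c in range(1, N_COLS + 1)
        }
    else:
        raise ValidationError(f"unknown dialect {dialect!r}, expected 'long' or 'wide'")

    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"{dialect} CSV missing columns: {sorted(missing_cols)}")

    if dialect == "wide":
        value_cols = [f"c{c}" for c in range(1, N_COLS + 1)]
        df = df.melt(
            id_vars=["sample_id", "treatment", "time_h", "row"],
            value_vars=value_cols,
            var_name="col",
            value_name="od590",
        )
        df["well_id"] = df["row"] + df["col"].str.lstrip("c")

    bad = pd.to_numeric(df["od590"], errors="coerce").isna() & df["od590"].notna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"non-numeric OD value {df['od590'].iloc[i]!r} at data row {i + 1}"
        )
    df["od590"] = pd.to_numeric(df["od590"])
    df["time_h"] = pd.to_numeric(df["time_h"])

    plates = []
    for (sample_id, treatment), rows in df.groupby(["sample_id", "treatment"], sort=True):
        plates.append(_assemble_plate(sample_id, treatment, rows, allow_missing))
    return plates


def read_plate_timeseries(
    path: str | io.TextIOBase,
    dialect: str = "long",
    allow_missing: bool = False,
) -> PlateTimeSeries:
    """Read a single-plate OD590 CSV; error if the file holds several samples."""
    plates = read_plates(path, dialect=dialect, allow_missing=allow_missing)
    if len(plates) != 1:
        raise ValidationError(
            f"expected exactly one plate in file, found {len(plates)} samples: "
            f"{[p.sample_id for p in plates]}"
        )
    return plates[0]


def _plate_to_long(ts: PlateTimeSeries) -> pd.DataFrame:
    long = (
        ts.od.rename_axis("well_id")
        .reset_index()
        .melt(id_vars="well_id", var_name="time_h", value_name="od590")
    )
    long.insert(0, "treatment", ts.treatment)
    long.insert(0, "sample_id", ts.sample_id)
    return long.sort_values(["time_h", "well_id"], kind="stable")


def _plate_to_wide(ts: PlateTimeSeries) -> pd.DataFrame:
    recs = []
    for t in ts.od.columns:
        for r in ROWS:
            rec = {
                "sample_id": ts.sample_id,
                "treatment": ts.treatment,
                "time_h": t,
                "row": r,
            }
            for c in range(1, N_COLS + 1):
                rec[f"c{c}"] = ts.od.at[f"{r}{c}", t]
            recs.append(rec)
    return pd.DataFrame.from_records(recs)


def write_plates(
    plates: list[PlateTimeSeries], path: str, dialect: str = "long"
) -> None:
    """Write plates to one CSV in the chosen dialect (bit-exact round trip)."""
    if dialect == "long":
        df = pd.concat([_plate_to_long(p) for p in plates], ignore_index=True)
    elif dialect == "wide":
        df = pd.concat([_plate_to_wide(p) for p in plates], ignore_index=True)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False)


def write_tidy(obj, path: str) -> None:
    """Write any tidy pipeline product (a DataFrame) as plain CSV.

    Floats are written with Python's shortest round-trip repr, so reading
    the file back reproduces every value exactly.
    """
    if not isinstance(obj, pd.DataFrame):
        raise ValidationError(
            f"write_tidy expects a DataFrame pipeline product, got {type(obj).__name__}"
        )
    obj.to_csv(path, index=False)


def read_tidy(path: str) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
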