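"""Indirect-calorimetry (IC) time-series containers, table IO, and QC.

Profiles hold one mouse's hourly activity (beam-break counts/hr) or food
intake (g/hr) trace expressed in zeitgeber time (ZT; hours since lights-on,
so ZT12 is lights-off under a 12:12 LD cycle).  Downstream phase estimation
works on a fixed 25-point canonical grid ZT6..ZT30 — recordings start five
hours before lights-off and run into the next morning, and hours recorded
after midnight of the light cycle (ZT0..ZT5) are mapped to ZT24..ZT29.

Three artefact-removal rules are applied before any phase analysis:

1. out-of-range values (food intake > 0.65 g/hr anywhere; activity
   > 4000 counts/hr during the light phase),
2. the lights-off transient: the ZT12 bin is dropped when it is a local
   maximum above 4/5 of the profile maximum with no competing local maximum
   between ZT12 and ZT17 (an unstable-lighting artefact),
3. pulse break-up: isolated spikes whose smaller gap to the two immediate
   neighbours reaches 0.57 x the profile maximum.

Removed and missing bins are linearly interpolated (edges extended) and the
curve is min-max scaled to [0, 1] before being fed to the phase network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCurveError,
    EmptyInputError,
    FormatError,
    InsufficientCoverageError,
)

#: Canonical hourly grid: ZT6 .. ZT30 inclusive (25 bins).
CANONICAL_ZT = np.arange(6.0, 31.0)
N_GRID = CANONICAL_ZT.size

#: Minimum number of observed canonical bins needed for imputation.
MIN_COVERAGE = 12

#: Minimum hours of data per profile for downstream prediction.
MIN_HOURS = 21

REQUIRED_COLUMNS = ("subject_id", "genotype", "centre", "modality", "time", "value")

MODALITIES = ("activity", "food_intake")

RULE_OUT_OF_RANGE = "out_of_range"
RULE_ZT12 = "zt12_artifact"
RULE_PULSE = "pulse_breakup"


@dataclass(frozen=True)
class CentreConfig:
    """Light schedule of a phenotyping centre; lights-on defines ZT0."""

    centre: str
    lights_on_clock: float
    lights_off_clock: float

    def clock_to_zt(self, clock_hour: float) -> float:
        return (clock_hour - self.lights_on_clock) % 24.0


#: Light schedules of the five supported phenotyping centres (12:12 LD).
KNOWN_CENTRES = {
    "WTSI": CentreConfig("WTSI", 7.5, 19.5),
    "TCP": CentreConfig("TCP", 7.0, 19.0),
    "ICS": CentreConfig("ICS", 7.0, 19.0),
    "RBRC": CentreConfig("RBRC", 11.0, 23.0),
    "HMGU": CentreConfig("HMGU", 6.0, 18.0),
}


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds of the three bad-data-point removal rules."""

    food_max: float = 0.65            # g/hr, applies at any ZT
    activity_max: float = 4000.0      # counts/hr, light phase only
    daytime_zt: tuple[float, float] = (0.0, 12.0)   # half-open [on, off)
    zt12_fraction: float = 4.0 / 5.0  # y12 must exceed this share of y_max
    zt12_window: tuple[float, float] = (12.0, 17.0)  # open interval
    alpha1: float = 0.57              # pulse-breakup threshold multiplier

    def __post_init__(self):
        if not (self.food_max > 0 and self.activity_max > 0 and self.alpha1 > 0):
            raise ValueError("thresholds must be positive")
        if not 0 < self.zt12_fraction < 1:
            raise ValueError("zt12_fraction must lie in (0, 1)")
        if not 0 < self.alpha1 < 1:
            raise ValueError("alpha1 must lie in (0, 1)")


@dataclass
class QCReport:
    """Log of removed points: (zt_hour, rule_id, original_value)."""

    removals: list[tuple[float, str, float]] = field(default_factory=list)

    def extend(self, other: "QCReport") -> None:
        self.removals.extend(other.removals)

    def __len__(self) -> int:
        return len(self.removals)

    def to_frame(self, subject_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.removals, columns=["zt_hour", "rule_id", "original_value"])
        if subject_id is not None:
            df.insert(0, "subject_id", subject_id)
        return df


@dataclass
class TimeSeriesProfile:
    """One mouse x modality hourly IC trace; missing values are NaN."""

    subject_id: str
    genotype: str
    centre: str
    modality: str
    zt: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.zt = np.asarray(self.zt, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.zt.shape != self.values.shape:
            raise ValueError("zt and values must have equal length")
        if np.any(np.diff(self.zt) <= 0):
            raise ValueError("zt hours must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        obs = self.values[~np.isnan(self.values)]
        if np.any(obs < 0):
            raise ValueError("non-missing values must be >= 0")

    @property
    def n_observed(self) -> int:
        return int(np.sum(~np.isnan(self.values)))

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _normalize_modality(raw: str) -> str:
    m = str(raw).strip().lower()
    if m in ("activity", "act"):
        return "activity"
    if m in ("food_intake", "food", "feeding"):
        return "food_intake"
    raise FormatError(f"unknown modality value {raw!r}")


def _parse_clock(text: str) -> float:
    """'HH:MM' (optionally HH:MM:SS) -> decimal clock hours."""
    parts = str(text).strip().split(":")
    try:
        h = float(parts[0])
        m = float(parts[1]) if len(parts) > 1 else 0.0
        s = float(parts[2]) if len(parts) > 2 else 0.0
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable clock time {text!r}") from exc
    return h + m / 60.0 + s / 3600.0


def read_ic_table(
    path,
    centre_cfg: CentreConfig | dict[str, CentreConfig] | None = None,
    time_format: str = "zt",
) -> list[TimeSeriesProfile]:
    """Read a delimited IC table into per-(subject, modality) profiles.

    Parameters
    ----------
    path : path-like or file-like
        Delimited text with header columns ``subject_id, genotype, centre,
        modality, time, value``.  The delimiter (comma/tab) is sniffed.
    centre_cfg : CentreConfig or mapping centre -> CentreConfig
        Needed when ``time_format == "clock"`` to convert clock hours to ZT
        (lights-on defines ZT0).  Defaults to the built-in centre table.
    time_format : {"zt", "clock"}
        "zt": decimal ZT hours.  "clock": HH:MM wall-clock time.

    Unparseable values become missing points; rows with unparseable times
    are dropped.
    """
    if time_format not in ("zt", "clock"):
        raise ValueError("time_format must be 'zt' or 'clock'")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError("input table has no content") from exc
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    if len(df) == 0:
        raise EmptyInputError("input table has no rows")

    df = df.copy()
    df["modality"] = df["modality"].map(_normalize_modality)
    df["value"] = pd.to_numeric(df["value"], errors="coerce")

    if time_format == "clock":
        cfg_map: dict[str, CentreConfig]
        if centre_cfg is None:
            cfg_map = KNOWN_CENTRES
        elif isinstance(centre_cfg, CentreConfig):
            cfg_map = {centre_cfg.centre: centre_cfg}
        else:
            cfg_map = dict(centre_cfg)

        def _to_zt(row):
            centre = str(row["centre"])
            if centre not in cfg_map:
                raise FormatError(f"no light schedule for centre {centre!r}")
            return cfg_map[centre].clock_to_zt(_parse_clock(row["time"]))

        df["zt"] = df.apply(_to_zt, axis=1)
    else:
        df["zt"] = pd.to_numeric(df["time"], errors="coerce")
        df = df[~df["zt"].isna()]

    profiles: list[TimeSeriesProfile] = []
    for (subject, modality), grp in df.groupby(["subject_id", "modality"], sort=True):
        grp = grp.sort_values("zt", kind="stable")
        zt = grp["zt"].to_numpy(dtype=float)
        vals = grp["value"].to_numpy(dtype=float)
        # collapse duplicate timestamps by their mean so zt stays strictly increasing
        if np.any(np.diff(zt) <= 0):
            uz, inv = np.unique(zt, return_inverse=True)
            sums = np.zeros_like(uz)
            counts = np.zeros_like(uz)
            ok = ~np.isnan(vals)
            np.add.at(sums, inv[ok], vals[ok])
            np.add.at(counts, inv[ok], 1.0)
            merged = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
            zt, vals = uz, merged
        profiles.append(
            TimeSeriesProfile(
                subject_id=str(subject),
                genotype=str(grp["genotype"].iloc[0]),
                centre=str(grp["centre"].iloc[0]),
                modality=modality,
                zt=zt,
                values=vals,
            )
        )
    return profiles


def to_canonical_grid(profile: TimeSeriesProfile) -> TimeSeriesProfile:
    """Resample a profile onto the canonical 25-point grid ZT6..ZT30.

    ZT hours below 6 are interpreted as the next morning and shifted by
    +24 h.  Samples are assigned to the hourly bin [k, k+1) and averaged
    within the bin; bins with no data are missing.
    """
    zt = np.where(profile.zt < CANONICAL_ZT[0], profile.zt + 24.0, profile.zt)
    bins = np.floor(zt).astype(int)
    in_range = (bins >= int(CANONICAL_ZT[0])) & (bins <= int(CANONICAL_ZT[-1]))

    sums = np.zeros(N_GRID)
    counts = np.zeros(N_GRID)
    idx = bins[in_range] - int(CANONICAL_ZT[0])
    vals = profile.values[in_range]
    ok = ~np.isnan(vals)
    np.add.at(sums, idx[ok], vals[ok])
    np.add.at(counts, idx[ok], 1.0)
    out = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)

    n_obs = int(np.sum(counts > 0))
    if n_obs < MIN_COVERAGE:
        raise InsufficientCoverageError(
            f"{profile.subject_id}/{profile.modality}: only {n_obs} non-missing "
            f"canonical bins (need >= {MIN_COVERAGE})"
        )
    return replace(profile, zt=CANONICAL_ZT.copy(), values=out)


# ---------------------------------------------------------------------------
# QC rules
# ---------------------------------------------------------------------------

def _observed_sequence(profile: TimeSeriesProfile):
    """Indices and values of the non-missing points in grid order."""
    mask = profile.observed_mask()
    return np.flatnonzero(mask), profile.values[mask]


def _local_max_positions(seq: np.ndarray) -> np.ndarray:
    """Interior indices of `seq` strictly greater than both neighbours."""
    if seq.size < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, seq.size - 1)
    is_max = (seq[interior] > seq[interior - 1]) & (seq[interior] > seq[interior + 1])
    return interior[is_max]


def remove_out_of_range(
    profile: TimeSeriesProfile, thr: QCThresholds = QCThresholds()
) -> tuple[TimeSeriesProfile, QCReport]:
    """Drop physiologically implausible values.

    Food intake above ``food_max`` is removed at any ZT; activity above
    ``activity_max`` is removed only during the light phase (ZT mod 24 in
    the half-open daytime interval).  Comparisons are strict.
    """
    values = profile.values.copy()
    report = QCReport()
    if profile.modality == "food_intake":
        bad = values > thr.food_max
    else:
        lo, hi = thr.daytime_zt
        day = ((profile.zt % 24.0) >= lo) & ((profile.zt % 24.0) < hi)
        bad = (values > thr.activity_max) & day
    bad &= ~np.isnan(values)
    for i in np.flatnonzero(bad):
        report.removals.append((float(profile.zt[i]), RULE_OUT_OF_RANGE, float(values[i])))
        values[i] = np.nan
    return replace(profile, values=values), report


def remove_zt12_artifact(
    profile: TimeSeriesProfile, thr: QCThresholds = QCThresholds()
) -> tuple[TimeSeriesProfile, QCReport]:
    """Drop the lights-off bin when it looks like a switching transient.

    The ZT12 value is removed iff it is (1) a local maximum, (2) above
    ``zt12_fraction`` of the profile maximum, and (3) the only local
    maximum with ZT strictly inside ``zt12_window``.
    """
    values = profile.values.copy()
    report = QCReport()
    at12 = np.flatnonzero(np.isclose(profile.zt % 24.0, 12.0) & ~np.isnan(values))
    if at12.size == 0:
        return replace(profile, values=values), report
    i12 = int(at12[0])

    idx, seq = _observed_sequence(profile)
    y_max = seq.max()
    local_max = idx[_local_max_positions(seq)]

    cond_local = i12 in local_max
    cond_height = values[i12] > thr.zt12_fraction * y_max
    lo, hi = thr.zt12_window
    others = [
        i for i in local_max
        if i != i12 and lo < (profile.zt[i] % 24.0) < hi
    ]
    cond_window = len(others) == 0

    if cond_local and cond_height and cond_window:
        report.removals.append((float(profile.zt[i12]), RULE_ZT12, float(values[i12])))
        values[i12] = np.nan
    return replace(profile, values=values), report


def remove_pulse_breakup(
    profile: TimeSeriesProfile, thr: QCThresholds = QCThresholds()
) -> tuple[TimeSeriesProfile, QCReport]:
    """Drop isolated spikes far from both immediate neighbours.

    For each observed point, y_diff = min over the adjacent observed
    neighbours of the absolute difference (endpoints use their single
    neighbour); the point is removed iff y_diff >= alpha1 * y_max.  All
    removals are evaluated on the incoming series (no cascade).
    """
    values = profile.values.copy()
    report = QCReport()
    idx, seq = _observed_sequence(profile)
    if seq.size < 2:
        return replace(profile, values=values), report
    y_max = seq.max()
    threshold = thr.alpha1 * y_max

    gaps = np.abs(np.diff(seq))
    left = np.concatenate([[np.inf], gaps])    # gap to previous neighbour
    right = np.concatenate([gaps, [np.inf]])   # gap to next neighbour
    y_diff = np.minimum(left, right)
    bad = y_diff >= threshold
    for pos in np.flatnonzero(bad):
        i = int(idx[pos])
        report.removals.append((float(profile.zt[i]), RULE_PULSE, float(seq[pos])))
        values[i] = np.nan
    return replace(profile, values=values), report


def apply_qc(
    profile: TimeSeriesProfile, thr: QCThresholds = QCThresholds()
) -> tuple[TimeSeriesProfile, QCReport]:
    """Run the three removal rules in their fixed order.

    Order matters: the profile maximum used by the ZT12 and pulse-breakup
    rules is computed after earlier removals.
    """
    report = QCReport()
    profile, r1 = remove_out_of_range(profile, thr)
    report.extend(r1)
    profile, r2 = remove_zt12_artifact(profile, thr)
    report.extend(r2)
    profile, r3 = remove_pulse_breakup(profile, thr)
    report.extend(r3)
    return profile, report


def impute_and_normalize(profile: TimeSeriesProfile) -> np.ndarray:
    """Linear-impute missing bins and min-max scale the curve to [0, 1].

    Interior gaps are linearly interpolated between the nearest observed
    neighbours; leading/trailing gaps take the nearest observed value.
    Requires at least MIN_COVERAGE observed bins; an all-constant curve
    has no usable range and raises DegenerateCurveError.
    """
    mask = profile.observed_mask()
    if int(mask.sum()) < MIN_COVERAGE:
        raise InsufficientCoverageError(
            f"{profile.subject_id}/{profile.modality}: "
            f"{int(mask.sum())} observed bins < {MIN_COVERAGE}"
        )
    full = np.interp(profile.zt, profile.zt[mask], profile.values[mask])
    return minmax_scale(full)


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Scale a complete curve (or rows of a matrix) to [0, 1]."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        lo, hi = values.min(), values.max()
        if hi == lo:
            raise DegenerateCurveError("curve has zero range")
        return (values - lo) / (hi - lo)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    if np.any(hi == lo):
        raise DegenerateCurveError("at least one curve has zero range")
    return (values - lo) / (hi - lo)


def write_ic_table(profiles: list[TimeSeriesProfile], path, sep: str = "\t") -> None:
    """Write profiles back out in the standard table dialect (ZT hours)."""
    rows = []
    for p in profiles:
        for z, v in zip(p.zt, p.values):
            rows.append((p.subject_id, p.genotype, p.centre, p.modality, z, v))
    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, sep=sep, index=False)
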