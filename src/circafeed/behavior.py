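"""Behavioral and biochemical appetite indices.

Implements the quantitative read-outs of circadian feeding studies in mice:

* caloric conversion of binned intake (chow/chocolate/cookie by energy
  density; lick counts pass through unconverted),
* conditioned-place-preference index with a pre-test bias filter,
* hedonic overconsumption (choice-condition total intake over homeostatic
  bland-item baseline, per time bin),
* hedonic preference fraction and cumulative 24-h intake,
* microdialysis fraction pooling and percent-change dopamine response,
* relative qPCR quantification by the delta-delta-Ct method, and the
  knockdown-efficiency inclusion filter used for virally injected animals.

Intake tables are long-format DataFrames with columns
``animal_id, group, item, bin_start, bin_width, amount, unit``; units are one
of ``g``, ``kcal``, ``licks``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    GridError,
    InsufficientFractionsError,
    MissingBinError,
    UndefinedPreferenceError,
    UnknownItemError,
)

__all__ = [
    "DEFAULT_DENSITIES",
    "CPPRecord",
    "DialysateSeries",
    "OverconsumptionProfile",
    "DDCtResult",
    "to_kcal",
    "intake_to_common_unit",
    "preference_index",
    "cpp_prebias_filter",
    "overconsumption",
    "preference_fraction",
    "cumulative_24h",
    "pool_dialysate",
    "percent_change",
    "ddct",
    "kd_inclusion",
]

#: Energy densities in kcal per gram. Breeding chow is 2988 kcal/kg; milk
#: chocolate drops 5.3 kcal/g; cookie 4.95 kcal/g. Liquids are measured in
#: licks and never converted.
DEFAULT_DENSITIES: dict[str, float] = {
    "chow": 2.988,
    "chocolate": 5.3,
    "cookie": 4.95,
}

INTAKE_COLUMNS = ("animal_id", "group", "item", "bin_start", "bin_width", "amount", "unit")
VALID_UNITS = ("g", "kcal", "licks")


@dataclass(frozen=True)
class CPPRecord:
    """Dwell times (seconds) for one conditioned-place-preference test."""

    animal_id: str
    phase: str  # 'pretest' | 'test'
    t_conditioned: float
    t_opposite: float
    t_neutral: float = 0.0

    def __post_init__(self):
        if min(self.t_conditioned, self.t_opposite, self.t_neutral) < 0:
            raise ValueError("dwell times must be non-negative")
        if self.t_conditioned + self.t_opposite + self.t_neutral <= 0:
            raise ValueError("at least one dwell time must be positive")


@dataclass(frozen=True)
class DialysateSeries:
    """Microdialysis fraction series around a snack presentation."""

    animal_id: str
    fraction_times: tuple  # minutes since session start, strictly increasing
    concentrations: tuple  # non-negative
    snack_time: float  # minutes

    def __post_init__(self):
        t = np.asarray(self.fraction_times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size:
            raise ValueError("fraction_times and concentrations differ in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("fraction times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class OverconsumptionProfile:
    """Per-bin ratio of choice-condition intake to homeostatic baseline.

    ``table`` has columns ``bin_start, ratio, undefined`` (plus ``animal_id``
    in animal-matched mode); ratios over a zero baseline are NaN with the
    ``undefined`` flag set rather than infinite.
    """

    table: pd.DataFrame
    baseline_source: str = "group-mean"
    unit: str = "kcal"

    @property
    def ratios(self) -> pd.Series:
        """Per-bin ratios (group-mean over animals in animal-matched mode)."""
        return self.table.groupby("bin_start")["ratio"].mean()


@dataclass(frozen=True)
class DDCtResult:
    """Relative expression by the delta-delta-Ct method."""

    fold_change: float
    dct_sample: float
    dct_calibrator: float


def to_kcal(amount_g: float, item: str, densities: dict[str, float] | None = None) -> float:
    """Convert grams of a food item to kilocalories via its energy density."""
    if amount_g < 0:
        raise ValueError("amount must be non-negative")
    densities = DEFAULT_DENSITIES if densities is None else densities
    if item not in densities:
        raise UnknownItemError(item)
    return amount_g * densities[item]


def intake_to_common_unit(
    df: pd.DataFrame, densities: dict[str, float] | None = None
) -> pd.DataFrame:
    """Convert gram rows to kcal; pass kcal and licks through unchanged.

    Returns a copy with ``amount``/``unit`` rewritten. A table may use either
    calories (foods) or licks (liquids), never both, because downstream
    ratios must be formed in a single common unit.
    """
    densities = DEFAULT_DENSITIES if densities is None else densities
    bad = set(df["unit"]) - set(VALID_UNITS)
    if bad:
        raise ValueError(f"invalid units {sorted(bad)}; expected one of {VALID_UNITS}")
    out = df.copy()
    grams = out["unit"] == "g"
    if grams.any():
        dens = out.loc[grams, "item"].map(densities)
        missing = out.loc[grams, "item"][dens.isna()]
        if not missing.empty:
            raise UnknownItemError(missing.iloc[0])
        out.loc[grams, "amount"] = out.loc[grams, "amount"] * dens
        out.loc[grams, "unit"] = "kcal"
    units = set(out["unit"])
    if len(units) > 1:
        raise ValueError(f"mixed units after conversion: {sorted(units)}")
    return out


def preference_index(
    rec: CPPRecord | None = None,
    *,
    t_conditioned: float | None = None,
    t_opposite: float | None = None,
    t_neutral: float = 0.0,
    include_neutral: bool = False,
) -> float:
    """Conditioned place preference index in [0, 1]; chance level is 0.5.

    Default (two-chamber) convention: time in the conditioned chamber over the
    summed time in the two conditioning chambers, so an indifferent animal
    scores exactly 0.5. With ``include_neutral=True`` the neutral corridor
    time enters the denominator as well.
    """
    if rec is not None:
        t_conditioned, t_opposite, t_neutral = rec.t_conditioned, rec.t_opposite, rec.t_neutral
    if t_conditioned is None or t_opposite is None:
        raise TypeError("provide a CPPRecord or explicit dwell times")
    denom = t_conditioned + t_opposite + (t_neutral if include_neutral else 0.0)
    if denom <= 0:
        raise UndefinedPreferenceError("all dwell times zero; PI undefined")
    return t_conditioned / denom


def cpp_prebias_filter(pretest_pi: float, lo: float = 0.35, hi: float = 0.65) -> bool:
    """Include an animal iff its pre-test PI lies in [lo, hi] (bounds inclusive).

    Animals with a strong innate side preference are excluded before
    conditioning to keep the paradigm unbiased.
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("require 0 <= lo < hi <= 1")
    return lo <= pretest_pi <= hi


def _bin_grid(df: pd.DataFrame) -> pd.DataFrame:
    return df[["bin_start", "bin_width"]].drop_duplicates().sort_values("bin_start")


def overconsumption(
    choice_bins: pd.DataFrame,
    baseline_bins: pd.DataFrame,
    densities: dict[str, float] | None = None,
    baseline_source: str = "group-mean",
) -> OverconsumptionProfile:
    """Choice-condition total intake over homeostatic baseline, per time bin.

    Per bin, the ratio is the summed caloric intake across all offered items
    under choice conditions divided by the bland-item (chow or water) intake
    under non-choice conditions; lick-based liquid series divide licks by
    licks. Values above 1 quantify hedonic overconsumption.

    ``baseline_source='group-mean'`` divides each animal's choice intake by
    the baseline-cohort mean in that bin (choice and baseline cohorts are
    distinct animals); ``'animal-matched'`` divides by the same animal's own
    baseline and requires matching animal_ids.
    """
    if baseline_source not in ("group-mean", "animal-matched"):
        raise ValueError("baseline_source must be 'group-mean' or 'animal-matched'")
    choice = intake_to_common_unit(choice_bins, densities)
    base = intake_to_common_unit(baseline_bins, densities)
    unit_c, unit_b = choice["unit"].iloc[0], base["unit"].iloc[0]
    if unit_c != unit_b:
        raise ValueError(f"choice ({unit_c}) and baseline ({unit_b}) units differ")

    grid_c, grid_b = _bin_grid(choice), _bin_grid(base)
    if not np.array_equal(grid_c.to_numpy(), grid_b.to_numpy()):
        raise MissingBinError(
            "choice and baseline tables must cover the same bin grid; got "
            f"{grid_c['bin_start'].tolist()} vs {grid_b['bin_start'].tolist()}"
        )

    # total choice intake per animal x bin, summed over items
    tot = (
        choice.groupby(["animal_id", "bin_start"], sort=True)["amount"].sum().reset_index()
    )
    if baseline_source == "group-mean":
        # baseline cohort mean intake per bin (mean of per-animal bin totals)
        base_per_bin = (
            base.groupby(["animal_id", "bin_start"])["amount"]
            .sum()
            .groupby("bin_start")
            .mean()
        )
        tot["baseline"] = tot["bin_start"].map(base_per_bin)
    else:
        base_pa = base.groupby(["animal_id", "bin_start"])["amount"].sum()
        idx = pd.MultiIndex.from_frame(tot[["animal_id", "bin_start"]])
        if not idx.isin(base_pa.index).all():
            raise MissingBinError("animal-matched baseline missing for some animal/bin pairs")
        tot["baseline"] = base_pa.reindex(idx).to_numpy()

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tot["amount"] / tot["baseline"]
    undefined = tot["baseline"] <= 0
    tot["ratio"] = ratio.where(~undefined, np.nan)
    tot["undefined"] = undefined
    cols = ["animal_id", "bin_start", "ratio", "undefined"]
    return OverconsumptionProfile(tot[cols], baseline_source=baseline_source, unit=unit_c)


def preference_fraction(hedonic: float, bland: float) -> float:
    """Hedonic share of total intake, hedonic / (hedonic + bland), in [0, 1]."""
    if hedonic < 0 or bland < 0:
        raise ValueError("intakes must be non-negative")
    total = hedonic + bland
    if total <= 0:
        raise UndefinedPreferenceError("total intake zero; preference undefined")
    return hedonic / total


def cumulative_24h(
    bins: pd.DataFrame, densities: dict[str, float] | None = None
) -> float | pd.Series:
    """Total intake over one day, in kcal for foods (licks for liquids).

    The bins of each animal must tile [0, 24) exactly — no gaps, no overlaps.
    Returns a scalar for a single animal, else a per-animal Series.
    """
    conv = intake_to_common_unit(bins, densities)
    for animal, sub in conv.groupby("animal_id"):
        grid = _bin_grid(sub).to_numpy(dtype=float)
        edges = np.concatenate([grid[:, 0], [grid[-1, 0] + grid[-1, 1]]])
        if not (
            np.isclose(edges[0], 0.0)
            and np.isclose(edges[-1], 24.0)
            and np.allclose(np.diff(grid[:, 0]), grid[:-1, 1])
        ):
            raise GridError(f"bins for animal {animal!r} do not tile [0, 24) exactly")
    totals = conv.groupby("animal_id")["amount"].sum()
    return float(totals.iloc[0]) if totals.size == 1 else totals


def pool_dialysate(series: DialysateSeries, k: int = 5) -> tuple[float, float]:
    """Mean of the k fractions before and the k after the snack time.

    Five 20-min fractions are pooled on each side by default, matching a 100-min
    baseline and response window. Uses the k fractions nearest the snack on
    each side; fractions collected exactly at the snack time are excluded.
    """
    t = np.asarray(series.fraction_times, dtype=float)
    c = np.asarray(series.concentrations, dtype=float)
    pre, post = c[t < series.snack_time], c[t > series.snack_time]
    if pre.size < k or post.size < k:
        raise InsufficientFractionsError(
            f"need >= {k} fractions on each side of the snack; "
            f"got {pre.size} before and {post.size} after"
        )
    return float(pre[-k:].mean()), float(post[:k].mean())


def percent_change(baseline: float, post: float) -> float:
    """100 * (post - baseline) / baseline; negative values indicate a decrease."""
    if baseline <= 0:
        raise ValueError("baseline must be positive for a percent change")
    return 100.0 * (post - baseline) / baseline


def ddct(ct_goi_s: float, ct_ref_s: float, ct_goi_c: float, ct_ref_c: float) -> DDCtResult:
    """Relative expression: fold = 2^-[(Ct_goi - Ct_ref)_sample - (Ct_goi - Ct_ref)_calibrator]."""
    cts = (ct_goi_s, ct_ref_s, ct_goi_c, ct_ref_c)
    if not all(np.isfinite(cts)):
        raise ValueError("all Ct values must be finite")
    dct_s = ct_goi_s - ct_ref_s
    dct_c = ct_goi_c - ct_ref_c
    return DDCtResult(
        fold_change=float(2.0 ** -(dct_s - dct_c)),
        dct_sample=float(dct_s),
        dct_calibrator=float(dct_c),
    )


def kd_inclusion(rel_expr: float, threshold: float = 0.5) -> bool:
    """Include a knockdown animal iff its residual expression shows *more than*
    ``threshold`` reduction versus control, i.e. rel_expr < 1 - threshold
    (strict)."""
    if rel_expr < 0:
        raise ValueError("relative expression must be non-negative")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return rel_expr < (1.0 - threshold)
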