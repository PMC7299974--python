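"""Seeded generators for synthetic circadian feeding-study data.

Every input the analysis pipeline consumes can be generated here with the
statistical structure such studies report: 6-h-binned chow/chocolate intake
peaking in the dark phase (acrophase ~ZT15), choice-condition overconsumption
elevated several-fold in the rest phase (peak ~ZT3), blunted rhythms in
clock-mutant genotypes, an expression matrix with ~10% rhythmic transcripts
clustered at two acrophases (~ZT3 and ~ZT16), CPP dwell-time tables, qPCR Ct
tables encoding known fold changes, and microdialysis dopamine series with a
morning-biased snack response.

Generators are pure functions of a :class:`SimConfig`: the same config (and
seed) reproduces byte-identical tables, and each generator draws from its own
random substream, so adding one call never perturbs another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .behavior import DEFAULT_DENSITIES, DialysateSeries
from .exceptions import ConfigError
from .transcriptome import ExpressionMatrix

__all__ = [
    "SimConfig",
    "gen_intake",
    "gen_expression",
    "gen_cpp",
    "gen_qpcr",
    "gen_dialysate",
]

# fixed substream ids: one per generator
_STREAM = {"intake": 1, "expression": 2, "cpp": 3, "qpcr": 4, "dialysate": 5}

_MUTANT_GENOTYPES = ("clock-mutant", "VTA-KD", "TH-KD")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for all synthetic generators.

    Defaults mirror the magnitudes such studies print: ad libitum chow around
    10 kcal/day (~3.5 g/day at 2.988 kcal/g) with a dark-phase intake peak at
    ZT15 (inside the ZT12-18 window), rest-phase overconsumption peaking
    4-fold (within the reported 2-7x range) at ZT3, cohorts of n=10, a
    transcriptome of 2000 genes with a 10% rhythmic fraction clustered at ZT3
    and ZT16 sampled at 4 timepoints x 4 replicates, ~70% viral knockdown,
    and a ~35% morning dopamine response to a chocolate snack.
    """

    seed: int = 0
    n_animals: int = 10
    genotype: str = "WT"  # WT | clock-mutant | VTA-KD | TH-KD
    light: str = "LD"  # LD | DD
    bins_per_day: int = 4
    # homeostatic chow intake, kcal per bin
    homeostatic_mesor: float = 2.5
    homeostatic_amplitude: float = 1.5
    homeostatic_acrophase: float = 15.0
    # hedonic overconsumption factor (dimensionless)
    overcons_peak_fold: float = 4.0
    overcons_acrophase: float = 3.0
    hedonic_share: float = 0.85
    mutant_damping: float = 1.0  # applied only to non-WT genotypes
    noise_sd: float = 0.25  # kcal per bin
    # transcriptome
    n_genes: int = 2000
    frac_rhythmic: float = 0.10
    cluster_phases: tuple[float, float] = (3.0, 16.0)
    cluster_sd: float = 0.75  # hours, spread of acrophases within a cluster
    expr_amplitude_range: tuple[float, float] = (0.3, 0.6)  # relative amplitude
    expr_noise_sd: float = 0.1  # relative to gene baseline
    n_replicates: int = 4
    zts: tuple[float, ...] = (1.0, 7.0, 13.0, 19.0)
    tissue: str = "VTA"
    # CPP
    cpp_test_pi: float = 0.70
    cpp_pretest_pi: float = 0.50
    cpp_pi_sd: float = 0.06
    cpp_session_s: float = 300.0
    # qPCR
    qpcr_fold: float = 0.3  # residual expression vs control (70% knockdown)
    ct_noise_sd: float = 0.05
    # microdialysis
    dial_baseline: float = 100.0
    dial_response_pct: float = 35.0  # morning snack response
    dial_response_night_pct: float = 0.0
    dial_noise_sd: float = 2.0
    n_dialysate_animals: int = 3

    def __post_init__(self):
        for name in ("frac_rhythmic", "hedonic_share", "mutant_damping"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.homeostatic_amplitude > self.homeostatic_mesor:
            raise ConfigError(
                "homeostatic_amplitude exceeds mesor; intake would go negative"
            )
        if self.overcons_peak_fold < 1.0:
            raise ConfigError("overcons_peak_fold must be >= 1")
        if self.bins_per_day < 2 or 24 % self.bins_per_day:
            raise ConfigError("bins_per_day must divide 24 and be >= 2")
        if self.n_genes < 10:
            raise ConfigError("n_genes must be >= 10")

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAM[stream]])


def _damping(config: SimConfig) -> float:
    """Residual rhythm amplitude multiplier: 1 for WT, 1 - damping for mutants."""
    if config.genotype == "WT":
        return 1.0
    if config.genotype not in _MUTANT_GENOTYPES:
        raise ConfigError(f"unknown genotype {config.genotype!r}")
    return 1.0 - config.mutant_damping


def homeostatic_profile(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Expected homeostatic chow intake (kcal/bin) at clock time t."""
    d = _damping(config)
    w = 2.0 * np.pi / 24.0
    return config.homeostatic_mesor + d * config.homeostatic_amplitude * np.cos(
        w * (np.asarray(t, dtype=float) - config.homeostatic_acrophase)
    )


def overconsumption_factor(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Expected choice/baseline intake ratio at clock time t.

    A raised cosine running from 1 (trough, active phase) to
    ``overcons_peak_fold`` (rest phase); clock-mutant damping flattens the
    oscillating part toward the mid value while preserving the mean.
    """
    d = _damping(config)
    w = 2.0 * np.pi / 24.0
    half_span = (config.overcons_peak_fold - 1.0) / 2.0
    return 1.0 + half_span * (
        1.0 + d * np.cos(w * (np.asarray(t, dtype=float) - config.overcons_acrophase))
    )


def gen_intake(config: SimConfig, densities: dict[str, float] | None = None) -> pd.DataFrame:
    """Binned intake table for a baseline cohort and a choice cohort.

    Baseline animals receive chow only; their per-bin intake is a
    zero-truncated Gaussian around the homeostatic cosine profile. Choice
    animals receive chow + chocolate; their total caloric intake is the same
    profile multiplied by the overconsumption factor, split between chocolate
    and chow by ``hedonic_share``. Amounts are emitted in grams (unit 'g') so
    downstream analysis exercises the caloric conversion.

    Columns: animal_id, group, condition, item, bin_start, bin_width, amount,
    unit. The two conditions use distinct animals, as when a separate
    non-choice cohort provides the homeostatic baseline.
    """
    densities = DEFAULT_DENSITIES if densities is None else densities
    rng = _rng(config, "intake")
    width = 24.0 / config.bins_per_day
    starts = np.arange(config.bins_per_day) * width
    mid = starts + width / 2.0
    homeo = homeostatic_profile(config, mid)
    factor = overconsumption_factor(config, mid)

    rows = []
    for cond in ("baseline", "choice"):
        group = f"{config.genotype}:{config.light}:{cond}"
        for i in range(config.n_animals):
            animal = f"{config.genotype}_{config.light}_{cond}_{i:02d}"
            noise = rng.normal(0.0, config.noise_sd, size=mid.size)
            if cond == "baseline":
                kcal = np.maximum(homeo + noise, 0.0)
                for s, a in zip(starts, kcal):
                    rows.append(
                        (animal, group, cond, "chow", s, width, a / densities["chow"], "g")
                    )
            else:
                total = np.maximum(homeo * factor + noise, 0.0)
                choc = config.hedonic_share * total
                chow = total - choc
                for s, kc_choc, kc_chow in zip(starts, choc, chow):
                    rows.append(
                        (animal, group, cond, "chocolate", s, width,
                         kc_choc / densities["chocolate"], "g")
                    )
                    rows.append(
                        (animal, group, cond, "chow", s, width,
                         kc_chow / densities["chow"], "g")
                    )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "group", "condition", "item", "bin_start", "bin_width",
                 "amount", "unit"],
    )


def gen_expression(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Gene x sample matrix with a planted rhythmic fraction, plus the truth.

    A ``frac_rhythmic`` subset of genes oscillates as a 24-h cosine whose
    acrophase is drawn from an equal-weight two-component circular mixture at
    ``cluster_phases`` (wrapped-Gaussian spread ``cluster_sd``); relative
    amplitudes are uniform on ``expr_amplitude_range``. The remaining genes
    are flat. Per-gene baselines are log-normal; noise is Gaussian relative to
    the baseline. Samples cover ``zts`` x ``n_replicates``.

    Returns (matrix, truth) where truth has per-gene columns ``is_rhythmic``,
    ``true_phase``, ``rel_amplitude``.
    """
    rng = _rng(config, "expression")
    n_g = config.n_genes
    genes = [f"g{i:05d}" for i in range(n_g)]
    sample_zt = np.repeat(config.zts, config.n_replicates)
    sample_rep = np.tile(np.arange(1, config.n_replicates + 1), len(config.zts))
    samples = [f"s{z:02.0f}_{r}" for z, r in zip(sample_zt, sample_rep)]

    n_r = int(round(config.frac_rhythmic * n_g))
    rhythmic_idx = rng.choice(n_g, size=n_r, replace=False)
    is_rhythmic = np.zeros(n_g, dtype=bool)
    is_rhythmic[rhythmic_idx] = True

    baseline = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=n_g)
    lo, hi = config.expr_amplitude_range
    rel_amp = np.where(is_rhythmic, rng.uniform(lo, hi, size=n_g), 0.0)
    cluster = rng.integers(0, 2, size=n_g)
    phase = np.mod(
        np.asarray(config.cluster_phases)[cluster] + rng.normal(0, config.cluster_sd, n_g),
        24.0,
    )
    phase = np.where(is_rhythmic, phase, np.nan)

    w = 2.0 * np.pi / 24.0
    osc = np.where(
        is_rhythmic[:, None],
        1.0 + rel_amp[:, None] * np.cos(w * (sample_zt[None, :] - phase[:, None])),
        1.0,
    )
    noise = rng.normal(0.0, config.expr_noise_sd, size=(n_g, len(samples)))
    values = baseline[:, None] * (osc + noise)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        samples=pd.DataFrame(
            {
                "zt": sample_zt,
                "replicate": sample_rep,
                "tissue": config.tissue,
                "genotype": config.genotype,
            },
            index=pd.Index(samples, name="sample"),
        ),
    )
    truth = pd.DataFrame(
        {"is_rhythmic": is_rhythmic, "true_phase": phase, "rel_amplitude": rel_amp},
        index=genes,
    )
    return matrix, truth


def gen_cpp(config: SimConfig) -> pd.DataFrame:
    """Pre-test and test dwell-time table for one CPP group.

    Pre-test preference indices are centred on ``cpp_pretest_pi`` (0.5 for an
    unbiased cohort); test PIs are centred on ``cpp_test_pi``. Sessions last
    ``cpp_session_s`` seconds with roughly a third spent in the neutral
    corridor; the remainder is split between the conditioned and opposite
    chambers according to the drawn PI.
    """
    rng = _rng(config, "cpp")
    rows = []
    for i in range(config.n_animals):
        animal = f"{config.genotype}_cpp_{i:02d}"
        for phase_label, pi_mean in (
            ("pretest", config.cpp_pretest_pi),
            ("test", config.cpp_test_pi),
        ):
            pi = float(np.clip(rng.normal(pi_mean, config.cpp_pi_sd), 0.02, 0.98))
            neutral = config.cpp_session_s / 3.0 * (1.0 + 0.1 * rng.normal())
            rest = config.cpp_session_s - neutral
            rows.append((animal, phase_label, pi * rest, (1.0 - pi) * rest, neutral))
    return pd.DataFrame(
        rows, columns=["animal_id", "phase", "t_conditioned", "t_opposite", "t_neutral"]
    )


def gen_qpcr(config: SimConfig, gene: str = "Bmal1", ref_gene: str = "Eef1a") -> pd.DataFrame:
    """Ct table encoding a known expression fold change against a reference.

    Knockdown samples express the target at ``qpcr_fold`` of control level,
    i.e. their target Ct sits ``-log2(qpcr_fold)`` cycles above the control
    mean, while the reference gene is invariant. Columns: sample, role
    ('sample' for knockdowns, 'calibrator' for controls), gene, ct.
    """
    rng = _rng(config, "qpcr")
    ct_ref, ct_goi = 18.0, 22.0
    shift = -np.log2(config.qpcr_fold)
    rows = []
    for role, n, goi_mean in (
        ("calibrator", config.n_animals, ct_goi),
        ("sample", config.n_animals, ct_goi + shift),
    ):
        for i in range(n):
            sid = f"{role}_{i:02d}"
            rows.append((sid, role, ref_gene, ct_ref + rng.normal(0, config.ct_noise_sd)))
            rows.append((sid, role, gene, goi_mean + rng.normal(0, config.ct_noise_sd)))
    return pd.DataFrame(rows, columns=["sample", "role", "gene", "ct"])


def gen_dialysate(config: SimConfig, session: str = "morning") -> list[DialysateSeries]:
    """Microdialysis series with a configurable snack-evoked dopamine change.

    Six 20-min fractions precede and six follow the snack; baseline levels
    vary between animals around ``dial_baseline`` and post-snack fractions are
    elevated by ``dial_response_pct`` percent in the morning session
    (``dial_response_night_pct`` at night, 0 by default).
    """
    if session not in ("morning", "night"):
        raise ConfigError("session must be 'morning' or 'night'")
    rng = _rng(config, "dialysate")
    resp = config.dial_response_pct if session == "morning" else config.dial_response_night_pct
    pre_times = 20.0 * np.arange(1, 7)  # 20..120 min
    post_times = 20.0 * np.arange(7, 13) + 10.0  # snack at 130 min
    out = []
    for i in range(config.n_dialysate_animals):
        c0 = config.dial_baseline * (1.0 + 0.05 * rng.normal())
        pre = np.maximum(c0 + rng.normal(0, config.dial_noise_sd, pre_times.size), 0.0)
        post = np.maximum(
            c0 * (1.0 + resp / 100.0) + rng.normal(0, config.dial_noise_sd, post_times.size),
            0.0,
        )
        out.append(
            DialysateSeries(
                animal_id=f"{session}_{i:02d}",
                fraction_times=tuple(np.concatenate([pre_times, post_times])),
                concentrations=tuple(np.concatenate([pre, post])),
                snack_time=130.0,
            )
        )
    return out
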