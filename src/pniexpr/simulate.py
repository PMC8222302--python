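"""Synthetic nCounter-style cohort generator.

Emulates a 45-sample perineural-invasion study cohort (9 Non-PNI, 11
Focal-PNI, 25 EXT-PNI) measured on a codeset of 740 endogenous genes, 30
housekeeping genes, 6 positive and 8 negative control probes.  Counts are
negative-binomial around per-gene log-normal baselines, multiplied by a
per-sample lane factor (hybridization/loading scale) and offset by a
Poisson background shared with the negative controls.  Differential
expression is planted in the EXT cohort only, in two effect tiers, so that
fold-change filters at 2x and 3x partition the planted genes cleanly; the
Focal and Non cohorts are exchangeable by construction.

All randomness derives from a single master seed through fixed named
substreams, so the per-gene baselines (and hence the probe identities of
planted effects) are shared between :func:`generate_cohort` and
:func:`generate_null_samples` at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, validate_annotation

# nCounter positive-control ERCC ladder concentrations (fM), probes A..F.
POSITIVE_LADDER_FM = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
# Counts per fM at lane factor 1; puts POS_A near 3200 counts.
POSITIVE_COUNTS_PER_FM = 25.0

_SUBSTREAM = {"baseline": 0, "cohort": 1, "null": 2, "clinical": 3}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study design this generator emulates: cohort
    sizes 9/11/25, a 740 + 30 gene codeset, 70 strongly (|log2FC| = 2.0)
    and 74 moderately (|log2FC| = 1.3) perturbed genes in the EXT cohort
    (so 70 genes survive a 3-fold filter and 144 a 2-fold filter), a small
    fraction of them down-regulated, and a nerve-tissue fraction covariate
    spanning 0.5-80% that is independent of expression.
    """

    n_non: int = 9
    n_focal: int = 11
    n_ext: int = 25
    n_endogenous: int = 740
    n_housekeeping: int = 30
    n_positive: int = 6
    n_negative: int = 8
    n_de_strong: int = 70
    n_de_moderate: int = 74
    frac_de_down: float = 0.06
    log2fc_strong: float = 2.0
    log2fc_moderate: float = 1.3
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.05
    hk_dispersion: float = 0.005
    lane_factor_sd: float = 0.3
    background_mean: float = 10.0
    nerve_fraction_range: tuple[float, float] = (0.005, 0.80)
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        for f in fields(self):
            if f.name in ("nerve_fraction_range",):
                continue
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v < 0:
                raise ValueError(f"GeneratorConfig.{f.name} must be nonnegative, got {v}")
        if self.n_de_strong + self.n_de_moderate > self.n_endogenous:
            raise ValueError(
                "GeneratorConfig: n_de_strong + n_de_moderate "
                f"({self.n_de_strong}+{self.n_de_moderate}) exceeds n_endogenous "
                f"({self.n_endogenous})"
            )
        if not 0 <= self.frac_de_down <= 1:
            raise ValueError("GeneratorConfig.frac_de_down must lie in [0, 1]")
        lo, hi = self.nerve_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("GeneratorConfig.nerve_fraction_range must satisfy 0<=lo<=hi<=1")
        if self.n_positive > len(POSITIVE_LADDER_FM):
            raise ValueError(
                f"GeneratorConfig.n_positive at most {len(POSITIVE_LADDER_FM)} ladder probes"
            )
        return self


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests."""

    de_gene_ids: list[str]
    true_log2fc: pd.Series  # indexed by de_gene_ids
    lane_factors: pd.Series  # indexed by sample id
    cohort_labels: pd.Series  # indexed by sample id

    strong_gene_ids: list[str] = field(default_factory=list)
    moderate_gene_ids: list[str] = field(default_factory=list)


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _SUBSTREAM[stream]])
    )


def _probe_ids(config: GeneratorConfig):
    endo = [f"GENE{i + 1:04d}" for i in range(config.n_endogenous)]
    hk = [f"HK{i + 1:02d}" for i in range(config.n_housekeeping)]
    pos = [f"POS_{chr(ord('A') + i)}" for i in range(config.n_positive)]
    neg = [f"NEG_{i + 1:02d}" for i in range(config.n_negative)]
    return endo, hk, pos, neg


def _baselines(config: GeneratorConfig):
    """Per-gene baseline means and planted-effect assignment (own substream).

    Shared between the cohort and the held-out null samples so both see the
    same codeset.
    """
    endo, hk, pos, neg = _probe_ids(config)
    rng = _rng(config, "baseline")
    base_endo = 2.0 ** rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                                  config.n_endogenous)
    # Housekeeping probes sit higher and tighter than endogenous genes:
    # codeset housekeeping genes are picked for robust, stable expression,
    # and must stay clear of the background floor.
    base_hk = 2.0 ** rng.normal(config.baseline_log_mean + 1.0,
                                config.baseline_log_sd / 2.0,
                                config.n_housekeeping)

    n_de = config.n_de_strong + config.n_de_moderate
    de_idx = rng.choice(config.n_endogenous, size=n_de, replace=False)
    strong_idx = de_idx[: config.n_de_strong]
    moderate_idx = de_idx[config.n_de_strong:]
    log2fc = np.zeros(config.n_endogenous)
    log2fc[strong_idx] = config.log2fc_strong
    log2fc[moderate_idx] = config.log2fc_moderate
    # A fixed fraction of planted genes flips to down-regulation in EXT.
    n_down = int(round(config.frac_de_down * n_de))
    if n_down:
        down_idx = rng.choice(de_idx, size=n_down, replace=False)
        log2fc[down_idx] *= -1.0
    return {
        "endo_ids": endo,
        "hk_ids": hk,
        "pos_ids": pos,
        "neg_ids": neg,
        "base_endo": base_endo,
        "base_hk": base_hk,
        "log2fc": log2fc,
        "strong_idx": strong_idx,
        "moderate_idx": moderate_idx,
        "de_idx": de_idx,
    }


def _draw_counts(config: GeneratorConfig, bl: dict, lane_factors: np.ndarray,
                 is_ext: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Raw counts for a batch of samples (probes x samples).

    Counts = NB(mean = baseline * fold * lane) + Poisson(background);
    controls carry no cohort effect and negatives are pure background.
    """
    n_samples = lane_factors.size

    def nb(mean, phi):
        if phi <= 0:
            return rng.poisson(mean)
        r = 1.0 / phi
        return rng.negative_binomial(r, r / (r + mean))

    fold = 2.0 ** np.outer(bl["log2fc"], np.where(is_ext, 1.0, 0.0))
    mu_endo = bl["base_endo"][:, None] * fold * lane_factors[None, :]
    mu_hk = bl["base_hk"][:, None] * np.ones(n_samples)[None, :] * lane_factors[None, :]
    counts_endo = (nb(mu_endo, config.nb_dispersion)
                   + rng.poisson(config.background_mean, mu_endo.shape))
    # Housekeeping probes vary technically, not biologically: the premise of
    # codeset-content normalization is that their expression is stable across
    # tumors, so they carry only a small residual overdispersion.
    counts_hk = (nb(mu_hk, config.hk_dispersion)
                 + rng.poisson(config.background_mean, mu_hk.shape))

    ladder = np.array(POSITIVE_LADDER_FM[: config.n_positive]) * POSITIVE_COUNTS_PER_FM
    mu_pos = ladder[:, None] * lane_factors[None, :] + config.background_mean
    counts_pos = rng.poisson(mu_pos)
    counts_neg = rng.poisson(config.background_mean,
                             (config.n_negative, n_samples))
    return np.vstack([counts_endo, counts_hk, counts_pos, counts_neg])


def _assemble(config: GeneratorConfig, bl: dict, counts: np.ndarray,
              sample_ids: list[str]) -> ExpressionMatrix:
    probe_ids = bl["endo_ids"] + bl["hk_ids"] + bl["pos_ids"] + bl["neg_ids"]
    classes = (["Endogenous"] * config.n_endogenous
               + ["Housekeeping"] * config.n_housekeeping
               + ["Positive"] * config.n_positive
               + ["Negative"] * config.n_negative)
    values = pd.DataFrame(counts.astype(np.int64), index=pd.Index(probe_ids, name="probe_id"),
                          columns=sample_ids)
    return ExpressionMatrix(values=values, probe_classes=pd.Series(classes, index=values.index))


def generate_cohort(config: GeneratorConfig | None = None
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate one synthetic cohort: counts, sample annotation, ground truth.

    Returns
    -------
    matrix : ExpressionMatrix
        Raw integer counts, 740+30+6+8 probes x 45 samples under defaults.
    annotation : pandas.DataFrame
        Indexed by sample id: cohort, nerve_fraction and clinical covariates.
    truth : GroundTruth
        Planted DE genes and effects, lane factors, cohort labels.
    """
    config = (config or GeneratorConfig()).validate()
    bl = _baselines(config)
    rng = _rng(config, "cohort")

    sample_ids = ([f"NON-{i + 1}" for i in range(config.n_non)]
                  + [f"FOCAL-{i + 1}" for i in range(config.n_focal)]
                  + [f"EXT-{i + 1}" for i in range(config.n_ext)])
    cohorts = np.array(["NON"] * config.n_non + ["FOCAL"] * config.n_focal
                       + ["EXT"] * config.n_ext)
    n_samples = len(sample_ids)

    lane = np.exp(rng.normal(0.0, config.lane_factor_sd, n_samples))
    counts = _draw_counts(config, bl, lane, cohorts == "EXT", rng)
    matrix = _assemble(config, bl, counts, sample_ids)

    # Nerve fraction is independent of expression by construction.
    lo, hi = config.nerve_fraction_range
    crng = _rng(config, "clinical")
    nerve = crng.uniform(lo, hi, n_samples)
    age = np.clip(np.round(crng.normal(70.0, 9.0, n_samples)), 38, 95)
    sex = crng.choice(["F", "M"], size=n_samples, p=[6 / 45, 39 / 45])
    site = crng.choice(["scalp", "ear_temple", "nose_midface", "lip", "neck"],
                       size=n_samples)
    width = np.clip(np.round(crng.normal(33.0, 12.0, n_samples)), 5, 90)
    thickness = np.clip(np.round(crng.normal(11.0, 4.0, n_samples)), 2, 30)
    rec_p = np.where(cohorts == "EXT", 14 / 25, 6 / 20)
    recurrence = crng.random(n_samples) < rec_p

    annotation = pd.DataFrame(
        {
            "cohort": cohorts,
            "nerve_fraction": nerve,
            "age": age.astype(int),
            "sex": sex,
            "site": site,
            "tumor_width_mm": width.astype(int),
            "tumor_thickness_mm": thickness.astype(int),
            "recurrence": recurrence,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    validate_annotation(annotation)

    de_ids = [bl["endo_ids"][i] for i in bl["de_idx"]]
    truth = GroundTruth(
        de_gene_ids=de_ids,
        true_log2fc=pd.Series(bl["log2fc"][bl["de_idx"]], index=de_ids),
        lane_factors=pd.Series(lane, index=sample_ids),
        cohort_labels=pd.Series(cohorts, index=sample_ids),
        strong_gene_ids=[bl["endo_ids"][i] for i in bl["strong_idx"]],
        moderate_gene_ids=[bl["endo_ids"][i] for i in bl["moderate_idx"]],
    )
    return matrix, annotation, truth


def generate_null_samples(config: GeneratorConfig | None = None, n: int = 0
                          ) -> ExpressionMatrix:
    """Draw ``n`` extra samples from the null (Non/Focal) distribution.

    Shares the per-gene baselines of :func:`generate_cohort` at the same
    seed, so these serve as held-out controls for score calibration.
    ``n = 0`` yields an empty matrix with the full probe index.
    """
    config = (config or GeneratorConfig()).validate()
    if n < 0:
        raise ValueError("n must be nonnegative")
    bl = _baselines(config)
    rng = _rng(config, "null")
    sample_ids = [f"NULL-{i + 1}" for i in range(n)]
    if n == 0:
        return _assemble(config, bl, np.zeros((len(bl["endo_ids"]) + len(bl["hk_ids"])
                                               + len(bl["pos_ids"]) + len(bl["neg_ids"]), 0),
                                              dtype=np.int64), sample_ids)
    lane = np.exp(rng.normal(0.0, config.lane_factor_sd, n))
    counts = _draw_counts(config, bl, lane, np.zeros(n, dtype=bool), rng)
    return _assemble(config, bl, counts, sample_ids)
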