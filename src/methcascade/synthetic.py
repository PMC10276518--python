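"""Synthetic plasma/tissue methylation cohorts with planted DMRs.

Emulates the statistical structure of a three-group plasma study (lung
cancer, benign lung disease, healthy) plus tumor-tissue and white-blood-cell
(WBC) reference samples:

* Each region has a healthy background methylation level ``bg_r`` drawn
  around a configurable mean; bisulfite counts are beta-binomial (binomial
  with a beta-distributed per-cell methylation probability), the standard
  overdispersed model for region-level methylation data.
* A subset of regions ("informative", the planted DMRs) is hypermethylated
  in tumor tissue at level ``tumor_beta_mean``.  Plasma from a cancer
  patient carries a latent circulating-tumor-DNA fraction ``f`` so its
  methylation mean is the dilution ``(1-f)*bg_r + f*tumor_beta_mean``.
  Benign patients show a configurable fraction of the cancer effect;
  healthy plasma and WBC sit at background; tumor tissue has ``f = 1``.
* Clinical covariates: TNM stage (cancer only), tumor size, histology,
  age, sex, smoking, and a serum CEA value drawn log-normally per group
  with weak separation (standalone AUC around 0.55-0.60 by default).

A companion qPCR simulator produces marker/reference Ct pairs whose marker
Ct decreases log2-linearly with the latent methylated-template abundance,
censored at the conventional 40-cycle detection limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import MethylationMatrix, QPCR_MAX_CYCLES

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_qpcr",
    "PLASMA_GROUPS",
    "TISSUE_GROUPS",
    "STAGES",
]

PLASMA_GROUPS = ("cancer", "benign", "healthy")
TISSUE_GROUPS = ("tumor", "wbc")
STAGES = ("I", "II", "III", "IV")
HISTOLOGIES = ("adenocarcinoma", "squamous", "small_cell", "large_cell")

# Region-level variation of the healthy background: beta concentration
# (a + b) used when jittering per-region background around the mean.
_BACKGROUND_CONCENTRATION = 100.0


class ConfigError(ValueError):
    """A simulation configuration field is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror a plasma marker-development study: 190/135/188
    cancer/benign/healthy training-scale plasma groups, 20+20 tissue
    references, a 165-region panel with 15 planted hypermethylated DMRs,
    ~2% healthy background AMF, 60% tumor-tissue methylation at informative
    regions, per-patient ctDNA fractions of 1-20% (a deliberately
    desk-informative range; a stress preset at 0.1-1% is available via
    ``replace``), and ~200 detected CpGs per region per sample.
    """

    n_cancer: int = 190
    n_benign: int = 135
    n_healthy: int = 188
    n_tumor_tissue: int = 20
    n_wbc: int = 20
    n_regions: int = 165
    n_true_dmr: int = 15
    healthy_beta_mean: float = 0.02
    healthy_beta_dispersion: float = 0.05
    tumor_beta_mean: float = 0.60
    tumor_fraction_range: tuple[float, float] = (0.01, 0.20)
    benign_effect_scale: float = 0.20
    coverage_mean: float = 200.0
    stage_distribution: dict = field(
        default_factory=lambda: {"I": 0.43, "II": 0.15, "III": 0.24, "IV": 0.18}
    )
    # Per-group log-normal CEA parameters (mu, sigma on the natural-log
    # scale, ng/mL).  The cancer shift gives a standalone AUC near 0.56.
    cea_params: dict = field(
        default_factory=lambda: {
            "cancer": (1.17, 0.80),
            "benign": (1.00, 0.80),
            "healthy": (1.00, 0.80),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_cancer", "n_benign", "n_healthy",
            "n_tumor_tissue", "n_wbc", "n_regions", "n_true_dmr",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_true_dmr > self.n_regions:
            raise ConfigError("n_true_dmr exceeds n_regions")
        for name in ("healthy_beta_mean", "tumor_beta_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0.0 < self.healthy_beta_dispersion < 1.0:
            raise ConfigError(
                f"healthy_beta_dispersion must lie in (0, 1), got {self.healthy_beta_dispersion!r}"
            )
        lo, hi = self.tumor_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError(
                f"tumor_fraction_range must be an interval within [0, 1], got {self.tumor_fraction_range!r}"
            )
        if not 0.0 <= self.benign_effect_scale <= 1.0:
            raise ConfigError(
                f"benign_effect_scale must lie in [0, 1], got {self.benign_effect_scale!r}"
            )
        if self.coverage_mean <= 0:
            raise ConfigError(f"coverage_mean must be positive, got {self.coverage_mean!r}")
        probs = np.array(list(self.stage_distribution.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ConfigError("stage_distribution must be a probability vector")

    def stress_preset(self) -> "SimulationConfig":
        """Low-tumor-fraction variant (0.1-1% ctDNA)."""
        return replace(self, tumor_fraction_range=(0.001, 0.01))


@dataclass
class SyntheticCohort:
    """One simulated study: counts, metadata, and generative ground truth."""

    counts: MethylationMatrix
    samples: pd.DataFrame            # indexed by sample id; includes 'group'
    truth: pd.Series                 # region -> bool, True = planted DMR
    tumor_fraction: pd.Series        # sample -> latent ctDNA fraction
    background: pd.Series            # region -> healthy background AMF
    latent_mu: pd.DataFrame          # sample x region latent methylation mean
    regions_bed: pd.DataFrame        # chrom/start/end/name/score/strand
    config: SimulationConfig

    @property
    def plasma_samples(self) -> pd.Index:
        return self.samples.index[self.samples["group"].isin(PLASMA_GROUPS)]

    @property
    def tissue_samples(self) -> pd.Index:
        return self.samples.index[self.samples["group"].isin(TISSUE_GROUPS)]


def _beta_binomial(rng, n, mu, rho):
    """Draw counts ~ BetaBinomial(n, mu, rho) elementwise.

    rho is the beta dispersion: p ~ Beta(a, b) with mean mu and
    a + b = (1 - rho) / rho; rho -> 0 recovers the plain binomial.
    """
    mu = np.clip(mu, 0.0, 1.0)
    conc = (1.0 - rho) / rho
    a = np.maximum(mu * conc, 1e-12)
    b = np.maximum((1.0 - mu) * conc, 1e-12)
    p = rng.beta(a, b)
    p = np.where(mu <= 0.0, 0.0, np.where(mu >= 1.0, 1.0, p))
    return rng.binomial(n, p)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort under the tumor-fraction dilution model.

    Deterministic: the same config (including seed) yields bit-identical
    output.  All randomness flows from one generator seeded with
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R = config.n_regions

    region_ids = [f"region_{i + 1:04d}" for i in range(R)]
    # Synthetic coordinates: 1 kb regions spaced 10 kb apart on one contig.
    starts = 10_000 * np.arange(R)
    regions_bed = pd.DataFrame(
        {
            "chrom": "chrS",
            "start": starts,
            "end": starts + 1_000,
            "name": region_ids,
            "score": 0,
            "strand": ".",
        }
    )

    informative = np.zeros(R, dtype=bool)
    informative[rng.choice(R, size=config.n_true_dmr, replace=False)] = True
    truth = pd.Series(
        informative, index=pd.Index(region_ids, name="region"), name="informative"
    )

    # Per-region background jittered around the configured mean.
    a = config.healthy_beta_mean * _BACKGROUND_CONCENTRATION
    b = (1.0 - config.healthy_beta_mean) * _BACKGROUND_CONCENTRATION
    if config.healthy_beta_mean in (0.0, 1.0):
        bg = np.full(R, config.healthy_beta_mean)
    else:
        bg = rng.beta(a, b, size=R)
    background = pd.Series(bg, index=region_ids, name="background")

    groups, sample_ids = [], []
    for grp, n in (
        ("cancer", config.n_cancer),
        ("benign", config.n_benign),
        ("healthy", config.n_healthy),
        ("tumor", config.n_tumor_tissue),
        ("wbc", config.n_wbc),
    ):
        for k in range(n):
            sample_ids.append(f"{grp}_{k + 1:04d}")
            groups.append(grp)
    groups = np.array(groups)
    N = len(sample_ids)

    lo, hi = config.tumor_fraction_range
    f = np.zeros(N)
    is_cancer = groups == "cancer"
    is_benign = groups == "benign"
    f[is_cancer] = rng.uniform(lo, hi, size=is_cancer.sum())
    f[is_benign] = config.benign_effect_scale * rng.uniform(lo, hi, size=is_benign.sum())
    f[groups == "tumor"] = 1.0
    tumor_fraction = pd.Series(f, index=sample_ids, name="tumor_fraction")

    # Latent methylation mean: dilution of tumor signal over background at
    # informative regions; background everywhere else.
    mu = np.tile(bg, (N, 1))
    effect = informative[None, :] * f[:, None]
    mu = (1.0 - effect) * mu + effect * config.tumor_beta_mean
    latent_mu = pd.DataFrame(mu, index=sample_ids, columns=region_ids)

    detected = rng.poisson(config.coverage_mean, size=(N, R))
    methylated = _beta_binomial(rng, detected, mu, config.healthy_beta_dispersion)
    counts = MethylationMatrix(
        pd.DataFrame(methylated, index=sample_ids, columns=region_ids),
        pd.DataFrame(detected, index=sample_ids, columns=region_ids),
    )
    counts.methylated.index.name = counts.detected.index.name = "sample"

    stage = np.full(N, "", dtype=object)
    n_cancer = int(is_cancer.sum())
    if n_cancer:
        stage_names = list(config.stage_distribution)
        probs = np.array([config.stage_distribution[s] for s in stage_names])
        stage[is_cancer] = rng.choice(stage_names, size=n_cancer, p=probs / probs.sum())

    tumor_size = np.full(N, np.nan)
    # Log-normal tumor diameters, median 2 cm (early-stage-weighted cohort).
    tumor_size[is_cancer] = rng.lognormal(np.log(2.0), 0.5, size=n_cancer)

    histology = np.full(N, "", dtype=object)
    histology[is_cancer] = rng.choice(
        HISTOLOGIES, size=n_cancer, p=[0.55, 0.25, 0.12, 0.08]
    )

    cea = np.full(N, np.nan)
    for grp, (mu_log, sd_log) in config.cea_params.items():
        mask = groups == grp
        cea[mask] = rng.lognormal(mu_log, sd_log, size=int(mask.sum()))

    samples = pd.DataFrame(
        {
            "group": groups,
            "stage": stage,
            "tumor_size_cm": tumor_size,
            "histology": histology,
            "age": np.round(rng.normal(60.0, 10.0, size=N)).astype(int),
            "sex": rng.choice(["F", "M"], size=N),
            "smoking": rng.choice(["never", "ever"], size=N, p=[0.55, 0.45]),
            "cea": cea,
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    return SyntheticCohort(
        counts=counts,
        samples=samples,
        truth=truth,
        tumor_fraction=tumor_fraction,
        background=background,
        latent_mu=latent_mu,
        regions_bed=regions_bed,
        config=config,
    )


def simulate_qpcr(
    cohort: SyntheticCohort,
    efficiency_noise: float = 0.15,
    markers=None,
    ct_reference_mean: float = 25.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a qPCR plate for the cohort's plasma and tissue samples.

    The marker Ct tracks the latent methylated-template abundance
    (proportional to the latent methylation mean): under perfect efficiency a
    doubling of abundance lowers Ct by one cycle.  ``efficiency_noise`` is
    the cycle-scale Gaussian jitter on each marker well.  The reference-gene
    Ct is independent of disease state.  Marker Ct values at or beyond cycle
    40 are censored at 40.

    Returns a long table with columns sample, marker, ct_marker,
    ct_reference.
    """
    if efficiency_noise < 0:
        raise ConfigError(f"efficiency_noise must be non-negative, got {efficiency_noise!r}")
    if markers is None:
        markers = list(cohort.counts.regions)
    rng = np.random.default_rng(
        cohort.config.seed + 1 if seed is None else seed
    )
    records = []
    mu = cohort.latent_mu
    for sid in cohort.samples.index:
        ct_ref = float(rng.normal(ct_reference_mean, 0.1))
        for m in markers:
            abundance = mu.at[sid, m]
            if abundance <= 0:
                ct = QPCR_MAX_CYCLES
            else:
                ct = ct_ref - np.log2(abundance) + rng.normal(0.0, efficiency_noise)
                ct = min(float(ct), QPCR_MAX_CYCLES)
            records.append((sid, m, ct, ct_ref))
    return pd.DataFrame(
        records, columns=["sample", "marker", "ct_marker", "ct_reference"]
    )
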