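"""Synthetic study generator with known ground truth.

Emulates the postpartum-cow study's inputs end to end so every pipeline
stage can be tested against a recorded truth:

* compositional genus abundances via a logistic-normal model (multivariate
  normal on latent logs, then closure), with factor-model blocks inducing
  controllable within-block correlations for the network stage;
* OSI phenotypes drawn from exactly the variance-component model the
  estimator assumes — y = X c + m + e with m ~ N(0, sigma2_m M), M built
  from the generated abundances — at a chosen true microbiability;
* LC-MS-like metabolite intensities with per-sample dilution factors, QC
  replicate injections at a chosen RSD, and QC-missing features to
  exercise the 50%-presence filter;
* a two-group (HOS/LOS) study bundle with planted differential taxa and
  metabolites and a local origin/pathway annotation table.

Cohort covariates mirror the study population: milk yield 36.9 +/- 8.04
kg/d, parity 2.75 +/- 0.94 (integer 1-5), body condition score
2.75 +/- 0.35 on the 1-5 scale.  One global seed is split into
per-stage substreams so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .metabolome import MetaboliteTable, OriginAnnotation, ORIGIN_CATEGORIES
from .microbiability import build_relationship_matrix
from .tables import SAMPLE_INDEX

# substream labels -> fixed offsets, so stage streams are independent of
# one another but fully determined by the global seed
_STAGE_KEY = {"abundance": 11, "phenotypes": 23, "metabolome": 37,
              "effects": 53, "annotation": 71}

#: cohort covariate distributions (mean, sd)
MILK_YIELD = (36.9, 8.04)
PARITY = (2.75, 0.94)
BCS = (2.75, 0.35)
MEAN_OSI = 0.66

#: default multiplicative HOS-vs-LOS effects planted on taxa
DEFAULT_TAXON_EFFECTS = [4.0, 4.0, 2.0, 0.5, 0.25, 0.25]
#: default log2 fold changes planted on metabolites (positive = higher in
#: HOS); magnitudes mirror typical differential-metabolite effect sizes
DEFAULT_METABOLITE_LOG2FC = [0.53, 0.51, 0.36, 1.20, 1.03,
                             -1.00, -0.74, -0.53, -0.36, -1.20]

_ORIGIN_PROBS = {  # proportions of a typical fecal metabolome annotation
    "host": 0.020, "microbiota": 0.072, "cometabolism": 0.167,
    "drug": 0.108, "food": 0.294, "environment": 0.008, "unknown": 0.331,
}

PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria",
         "Tenericutes", "Verrucomicrobia", "Spirochaetes",
         "Candidatus_Saccharibacteria")


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEY[stage],))
    )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    seed: int
    true_microbiability: float | None = None
    covariate_effects: dict = field(default_factory=dict)
    differential_taxa: list = field(default_factory=list)  # (taxon, fold)
    differential_metabolites: list = field(default_factory=list)  # (feature, log2fc)
    dilution_factors: dict = field(default_factory=dict)
    correlation_blocks: list = field(default_factory=list)  # (taxa, rho)
    sigma2_m: float | None = None
    sigma2_e: float | None = None
    microbial_effect: dict = field(default_factory=dict)
    residual: dict = field(default_factory=dict)
    planned_los: list = field(default_factory=list)
    planned_hos: list = field(default_factory=list)

    def __post_init__(self):
        if self.true_microbiability is not None and not (
            0 <= self.true_microbiability <= 1
        ):
            raise ValueError("true_microbiability must lie in [0, 1]")
        if any(d <= 0 for d in self.dilution_factors.values()):
            raise ValueError("dilution factors must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_abundance_table(
    n_samples: int,
    n_taxa: int,
    correlation_blocks: list[tuple[list, float]] | None = None,
    seed: int = 0,
    log_mean_range: tuple[float, float] = (np.log(1e-5), np.log(5e-2)),
    log_sd: float = 0.6,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Logistic-normal genus relative abundances with correlation blocks.

    Latent per-taxon log-abundances are mu_a + log_sd * z_ia, with z from
    a one-factor-per-block model giving the requested within-block
    correlation; rows are closed to sum to 1.  Taxon base means are
    log-uniform over ``log_mean_range`` (spanning > 3 orders of
    magnitude, so the 0.01% prevalence filter has work to do).
    """
    if n_samples < 2 or n_taxa < 2:
        raise ValueError("need n_samples >= 2 and n_taxa >= 2")
    taxa = [f"g{i:03d}" for i in range(1, n_taxa + 1)]
    blocks = []
    for members, rho in (correlation_blocks or []):
        members = [m if isinstance(m, str) else taxa[m] for m in members]
        unknown = [m for m in members if m not in taxa]
        if unknown:
            raise ValueError(f"correlation block references unknown taxa: {unknown}")
        if not 0 <= rho < 1:
            raise ValueError("block correlation must lie in [0, 1)")
        blocks.append((members, float(rho)))

    rng = _rng(seed, "abundance")
    mu = rng.uniform(*log_mean_range, size=n_taxa)
    z = rng.standard_normal((n_samples, n_taxa))
    col = {t: i for i, t in enumerate(taxa)}
    for members, rho in blocks:
        f = rng.standard_normal(n_samples)
        for m in members:
            j = col[m]
            z[:, j] = np.sqrt(rho) * f + np.sqrt(1 - rho) * z[:, j]
    latent = np.exp(mu + log_sd * z)
    abundances = latent / latent.sum(axis=1, keepdims=True)
    table = pd.DataFrame(
        abundances,
        index=pd.Index([f"cow{i:03d}" for i in range(1, n_samples + 1)],
                       name=SAMPLE_INDEX),
        columns=taxa,
    )
    truth = SyntheticTruth(seed=seed, correlation_blocks=[(m, r) for m, r in blocks])
    return table, truth


def simulate_phenotypes(
    abundance: pd.DataFrame,
    true_microbiability: float,
    covariate_effects: dict | None = None,
    total_variance: float = 0.09,
    mean_phenotype: float = MEAN_OSI,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Phenotypes under the microbiability model at a known truth.

    The microbial effect is drawn with covariance sigma2_m * M where M is
    the relationship matrix of ``abundance`` and
    sigma2_m = true_microbiability * total_variance; the residual carries
    the remaining variance.  Covariates (parity, milk yield, body
    condition) are generated, centered, and contribute through
    ``covariate_effects`` slopes (phenotype units per covariate unit).

    OSI is the raw model draw (it is not clipped — clipping would bias
    variance-component recovery); the TOS concentration is left missing
    on the rare samples whose drawn OSI is non-positive.
    """
    if not 0 <= true_microbiability <= 1:
        raise ValueError("true_microbiability must lie in [0, 1]")
    if covariate_effects is None:
        covariate_effects = {"parity": 0.02, "milk_yield": 0.005}
    n = abundance.shape[0]
    M = build_relationship_matrix(abundance)
    rng = _rng(seed, "phenotypes")

    parity = np.clip(np.rint(rng.normal(*PARITY, size=n)), 1, 5).astype(int)
    milk = rng.normal(*MILK_YIELD, size=n)
    bcs = np.clip(rng.normal(*BCS, size=n), 1.0, 5.0)
    covariates = pd.DataFrame(
        {"parity": parity, "milk_yield": milk, "bcs": bcs}, index=abundance.index
    )

    sigma2_m = true_microbiability * total_variance
    sigma2_e = (1.0 - true_microbiability) * total_variance
    d, U = np.linalg.eigh(M.matrix)
    L = U * np.sqrt(np.clip(d, 0.0, None))
    m = np.sqrt(sigma2_m) * (L @ rng.standard_normal(n))
    e = np.sqrt(sigma2_e) * rng.standard_normal(n)

    fixed = np.full(n, mean_phenotype)
    for cov, slope in covariate_effects.items():
        vals = covariates[cov].to_numpy(dtype=float)
        fixed = fixed + slope * (vals - vals.mean())
    y = fixed + m + e

    taoc = np.clip(rng.normal(0.52, 0.03, size=n), 0.40, None)  # mM
    tos = np.where(y > 0, y * taoc * 1000.0, np.nan)  # uM
    phenotypes = covariates.assign(
        **{"T-AOC": taoc, "TOS": tos, "OSI": y}
    )
    truth = SyntheticTruth(
        seed=seed,
        true_microbiability=true_microbiability,
        covariate_effects=dict(covariate_effects),
        sigma2_m=sigma2_m,
        sigma2_e=sigma2_e,
        microbial_effect=dict(zip(abundance.index, m.tolist())),
        residual=dict(zip(abundance.index, e.tolist())),
    )
    return phenotypes, truth


def simulate_metabolome(
    n_samples: int,
    n_qc: int = 6,
    n_features: int = 300,
    dilution_range: tuple[float, float] = (0.5, 2.0),
    qc_rsd: float = 0.10,
    noise_cv: float = 0.15,
    missing_qc_fraction: float = 0.05,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    dilution_factors: list[float] | None = None,
    base_log2fc: dict[str, np.ndarray] | None = None,
) -> tuple[MetaboliteTable, SyntheticTruth]:
    """Intensity table with dilution factors and QC replicate injections.

    Each biological sample is (base profile x per-sample dilution) x
    multiplicative lognormal noise of coefficient of variation
    ``noise_cv``; QC samples are the base profile with CV ``qc_rsd``.
    ``missing_qc_fraction`` of features are blanked in > 50% of the QC
    injections so the presence filter fires.  ``base_log2fc`` optionally
    maps sample ids to per-feature log2 shifts (used to plant group
    effects).
    """
    if n_qc < 3:
        raise ValueError("need at least 3 QC samples")
    lo, hi = dilution_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("dilution_range must be positive and ordered")
    rng = _rng(seed, "metabolome")
    features = [f"m{i:04d}" for i in range(1, n_features + 1)]
    if sample_ids is None:
        sample_ids = [f"cow{i:03d}" for i in range(1, n_samples + 1)]
    if len(sample_ids) != n_samples:
        raise ValueError("sample_ids length mismatch")
    qc_ids = [f"QC{i}" for i in range(1, n_qc + 1)]

    base = np.exp(rng.uniform(np.log(1e4), np.log(1e7), size=n_features))
    if dilution_factors is None:
        dilution = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    else:
        dilution = np.asarray(dilution_factors, dtype=float)
        if (dilution <= 0).any():
            raise ValueError("dilution factors must be positive")
    sigma = np.sqrt(np.log1p(noise_cv**2))
    bio = np.empty((n_samples, n_features))
    for i, sid in enumerate(sample_ids):
        profile = base.copy()
        if base_log2fc and sid in base_log2fc:
            profile = profile * np.exp2(base_log2fc[sid])
        noise = np.exp(sigma * rng.standard_normal(n_features)) if sigma > 0 else 1.0
        bio[i] = profile * dilution[i] * noise

    sigma_qc = np.sqrt(np.log1p(qc_rsd**2))
    qc = np.empty((n_qc, n_features))
    for i in range(n_qc):
        noise = np.exp(sigma_qc * rng.standard_normal(n_features)) if sigma_qc > 0 else 1.0
        qc[i] = base * noise

    n_missing = int(np.floor(missing_qc_fraction * n_features))
    missing_feats = rng.choice(n_features, size=n_missing, replace=False)
    n_blank = int(np.floor(n_qc * 0.5)) + 1  # > 50% of QC injections
    for j in missing_feats:
        rows = rng.choice(n_qc, size=n_blank, replace=False)
        qc[rows, j] = np.nan

    intensities = pd.DataFrame(
        np.vstack([bio, qc]),
        index=pd.Index(sample_ids + qc_ids, name=SAMPLE_INDEX),
        columns=features,
    )
    table = MetaboliteTable(intensities=intensities, qc_samples=qc_ids)
    truth = SyntheticTruth(
        seed=seed, dilution_factors=dict(zip(sample_ids, dilution.tolist()))
    )
    return table, truth


@dataclass
class StudySpec:
    """Study-shape parameters; defaults mirror the cohort design
    (63 cows, OSI extremes of 9 + 9, genus-level table)."""

    n_cohort: int = 63
    k: int = 9
    n_taxa: int = 150
    true_microbiability: float = 0.431
    total_variance: float = 0.09
    covariate_effects: dict = field(default_factory=lambda: {"parity": 0.02,
                                                             "milk_yield": 0.005})
    correlation_blocks: list = field(default_factory=lambda: [
        (["g001", "g002", "g003", "g004", "g005", "g006"], 0.97),
        (["g010", "g011", "g012", "g013", "g014"], 0.95),
        (["g020", "g021", "g022", "g023", "g024"], 0.90),
    ])
    taxon_effects: list = None  # [(taxon, fold)] planted in HOS
    n_metabolite_features: int = 300
    n_qc: int = 6
    qc_rsd: float = 0.10
    metabolite_noise_cv: float = 0.15
    dilution_range: tuple = (0.5, 2.0)
    metabolite_log2fc: list = None  # [(feature, log2fc)] planted in HOS
    n_pathways: int = 15

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("group size k must be >= 3")
        if 2 * self.k > self.n_cohort:
            raise ValueError("2k exceeds the cohort size")
        # taxon_effects None means "assign the default folds to
        # mid-abundance taxa once the table is generated"
        if self.metabolite_log2fc is None:
            self.metabolite_log2fc = [
                (f"m{i + 1:04d}", lfc)
                for i, lfc in enumerate(DEFAULT_METABOLITE_LOG2FC)
            ]


@dataclass
class StudyBundle:
    abundance: pd.DataFrame
    phenotypes: pd.DataFrame
    metabolome: MetaboliteTable
    annotation: OriginAnnotation
    taxon_meta: pd.DataFrame  # phylum per taxon
    groups: pd.Series  # planned LOS/HOS labels over metabolome samples
    truth: SyntheticTruth


def simulate_two_group_study(spec: StudySpec | None = None, seed: int = 0) -> StudyBundle:
    """Full HOS/LOS study emulation with planted effects.

    Generates the cohort abundance table and phenotypes, designates the k
    lowest / highest OSI samples as the planned LOS / HOS groups (so one
    group's OSI stochastically dominates the other's by construction),
    multiplies the planted taxa in HOS samples before re-closure, and
    simulates a metabolome for the selected animals with planted log2
    fold changes plus an origin/pathway annotation whose "glutathione
    synthesis" pathway collects the planted metabolites.
    """
    spec = spec or StudySpec()
    abundance, ab_truth = simulate_abundance_table(
        spec.n_cohort, spec.n_taxa, spec.correlation_blocks, seed=seed
    )
    taxon_effects = spec.taxon_effects
    if taxon_effects is None:
        # plant the default folds on observable (mid-abundance) taxa that
        # survive the prevalence filter and sit outside the correlation
        # blocks, so differential and network signals stay separable
        blocked = {t for members, _ in ab_truth.correlation_blocks
                   for t in members}
        ranked = abundance.mean(axis=0).sort_values(ascending=False).index
        free = [t for t in ranked if t not in blocked]
        picked = free[10:10 + len(DEFAULT_TAXON_EFFECTS)]
        taxon_effects = list(zip(picked, DEFAULT_TAXON_EFFECTS))
    unknown = [t for t, _ in taxon_effects if t not in abundance.columns]
    if unknown:
        raise ValueError(f"taxon effects reference unknown taxa: {unknown}")
    phenotypes, ph_truth = simulate_phenotypes(
        abundance, spec.true_microbiability, spec.covariate_effects,
        spec.total_variance, seed=seed,
    )
    order = phenotypes["OSI"].sort_values(kind="mergesort").index
    planned_los = list(order[: spec.k])
    planned_hos = list(order[-spec.k:])

    # differential taxa shift with oxidative-stress state: the planted
    # fold applies to every above-median-OSI animal (so any extreme HOS
    # group carries the full effect, any LOS group none), then re-close
    high_state = list(order[spec.n_cohort // 2:])
    planted = abundance.copy()
    for taxon, fold in taxon_effects:
        planted.loc[high_state, taxon] *= fold
    planted = planted.div(planted.sum(axis=1), axis=0)

    selected = planned_los + planned_hos
    groups = pd.Series("LOS", index=selected, name="group")
    groups.loc[planned_hos] = "HOS"

    features = [f"m{i:04d}" for i in range(1, spec.n_metabolite_features + 1)]
    unknown_m = [f for f, _ in spec.metabolite_log2fc if f not in features]
    if unknown_m:
        raise ValueError(f"metabolite effects reference unknown features: {unknown_m}")
    shift = np.zeros(spec.n_metabolite_features)
    feat_pos = {f: i for i, f in enumerate(features)}
    for feat, lfc in spec.metabolite_log2fc:
        shift[feat_pos[feat]] = lfc
    base_log2fc = {sid: shift for sid in planned_hos}
    metabolome, met_truth = simulate_metabolome(
        n_samples=len(selected),
        n_qc=spec.n_qc,
        n_features=spec.n_metabolite_features,
        dilution_range=spec.dilution_range,
        qc_rsd=spec.qc_rsd,
        noise_cv=spec.metabolite_noise_cv,
        seed=seed,
        sample_ids=selected,
        base_log2fc=base_log2fc,
    )

    rng = _rng(seed, "annotation")
    cats = list(_ORIGIN_PROBS)
    probs = np.array([_ORIGIN_PROBS[c] for c in cats])
    origins = pd.Series(
        rng.choice(cats, size=len(features), p=probs / probs.sum()),
        index=features, name="origin",
    )
    pathway_ids = [f"pw{i:02d}" for i in range(1, spec.n_pathways + 1)]
    pathways: dict[str, set] = {}
    for feat in features:
        n_member = rng.poisson(1.0)
        pathways[feat] = set(rng.choice(pathway_ids, size=min(n_member, spec.n_pathways),
                                        replace=False))
    # planted metabolites share a pathway (and a microbial/cometabolic origin),
    # mimicking the glutathione-synthesis amino-acid cluster
    target_pw = "pw_glutathione"
    for i, (feat, _) in enumerate(spec.metabolite_log2fc):
        pathways[feat].add(target_pw)
        origins[feat] = "microbiota" if i % 2 == 0 else "cometabolism"
    extra = rng.choice(
        [f for f in features if f not in dict(spec.metabolite_log2fc)],
        size=5, replace=False,
    )
    for feat in extra:
        pathways[feat].add(target_pw)
    annotation = OriginAnnotation(origins=origins, pathways=pathways)

    phyla = pd.Series(rng.choice(PHYLA, size=spec.n_taxa), index=abundance.columns,
                      name="phylum")
    taxon_meta = phyla.to_frame()

    truth = SyntheticTruth(
        seed=seed,
        true_microbiability=spec.true_microbiability,
        covariate_effects=dict(spec.covariate_effects),
        differential_taxa=[(t, f) for t, f in taxon_effects],
        differential_metabolites=[(f, l) for f, l in spec.metabolite_log2fc],
        dilution_factors=met_truth.dilution_factors,
        correlation_blocks=ab_truth.correlation_blocks,
        sigma2_m=ph_truth.sigma2_m,
        sigma2_e=ph_truth.sigma2_e,
        planned_los=planned_los,
        planned_hos=planned_hos,
    )
    return StudyBundle(
        abundance=planted,
        phenotypes=phenotypes,
        metabolome=metabolome,
        annotation=annotation,
        taxon_meta=taxon_meta,
        groups=groups,
        truth=truth,
    )
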