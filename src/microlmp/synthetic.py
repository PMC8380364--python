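"""Synthetic cohorts with planted ground truth.

Generates zero-inflated compositional OTU tables plus phenotypes so every
downstream stage (association scan, enterotyping, co-abundance groups,
network topology) can be validated against a known answer:

* **basis abundances** are log-normal — a Gaussian copula on the log scale
  carrying a block-structured "basis" correlation matrix (the ground truth
  the compositional correlation estimator must recover);
* **enterotype structure** comes from a two-(or more-)component mixture:
  each component multiplies the abundance of its dominant taxa by a fold
  change, mimicking Prevotella- vs Treponema-dominated communities;
* **counts** are a multinomial draw at fixed sequencing depth from the
  closed (sum-to-one) basis composition, followed by per-taxon dropout
  (detection failure independent of composition);
* **phenotype** (lean meat percentage) is an additive model on sex, batch,
  and per-taxon presence/abundance effects — the generative counterpart of
  the two-part association model.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phenotype import LMP_BF_COEF, LMP_INTERCEPT, LMP_LMA_COEF, LMP_SCALE
from .tables import OtuTable, TaxonomyMap, write_otu_table, write_taxonomy

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "ConfigError",
    "build_basis_correlation",
    "simulate_counts",
    "simulate_phenotype",
    "simulate_dataset",
    "write_dataset",
]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic cohort.

    Parameters
    ----------
    n_samples, n_taxa, sequencing_depth
        Cohort size, taxon count and multinomial reads per sample.
    correlation_blocks
        List of ``(member_indices, rho)``: taxa in one block share pairwise
        basis correlation ``rho`` on the log scale. Memberships must be
        disjoint. Equicorrelation below ``-1/(m-1)`` is not realisable for a
        block of size ``m``; the PSD repair step then projects it back.
    enterotype_components
        List of ``(weight, dominant_indices, fold_change)``: a sample drawn
        from a component has the log-mean of that component's dominant taxa
        shifted by ``log(fold_change)``. Weights must sum to 1.
    effect_taxa
        List of ``(taxon_index, beta1, beta2)``: additive phenotype effects
        of the taxon's presence (``beta1``, phenotype units) and of its
        standardized log10 abundance among detected samples (``beta2``).
    sex_effect, batch_effects, residual_sd
        Phenotype covariate model: additive sex effect (M vs F), one offset
        per batch, and Gaussian residual standard deviation.
    zero_inflation
        Per-taxon extra dropout probability (scalar or length-``n_taxa``).
    log_mean_sd, log_sd
        Spread of per-taxon baseline log-means (creates abundant and rare
        taxa) and the within-taxon log-scale standard deviation.
    """

    n_samples: int = 300
    n_taxa: int = 120
    sequencing_depth: int = 20_000
    correlation_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    enterotype_components: list[tuple[float, list[int], float]] = field(default_factory=list)
    effect_taxa: list[tuple[int, float, float]] = field(default_factory=list)
    sex_effect: float = 1.0
    batch_effects: tuple[float, ...] = (0.0,)
    residual_sd: float = 1.0
    phenotype_intercept: float = 55.0
    zero_inflation: float | np.ndarray = 0.0
    log_mean_sd: float = 1.5
    log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ConfigError("need at least 2 taxa")
        if self.sequencing_depth <= 0:
            raise ConfigError("sequencing_depth must be positive")
        seen: set[int] = set()
        for members, rho in self.correlation_blocks:
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"block correlation {rho} outside [-1, 1]")
            for m in members:
                if not 0 <= m < self.n_taxa:
                    raise ConfigError(f"block member {m} out of range")
                if m in seen:
                    raise ConfigError(f"taxon {m} appears in two blocks")
                seen.add(m)
        if self.enterotype_components:
            w = sum(c[0] for c in self.enterotype_components)
            if abs(w - 1.0) > 1e-9:
                raise ConfigError(f"mixture weights sum to {w}, expected 1")
        for t, _, _ in self.effect_taxa:
            if not 0 <= t < self.n_taxa:
                raise ConfigError(f"effect taxon {t} not in the table")
        zi = np.broadcast_to(np.asarray(self.zero_inflation, dtype=float), (self.n_taxa,))
        if ((zi < 0) | (zi > 1)).any():
            raise ConfigError("zero_inflation must lie in [0, 1]")

    def taxon_ids(self) -> list[str]:
        return [f"OTU{i + 1}" for i in range(self.n_taxa)]

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @classmethod
    def default_fixture(cls, seed: int = 0) -> "SimulationConfig":
        """The package's reference cohort: 300 samples x 120 taxa at depth
        20,000 with two enterotype components (60/40), three correlation
        blocks (rho = 0.7, 0.7, -0.5) and five phenotype-effect taxa."""
        return cls(
            n_samples=300,
            n_taxa=120,
            sequencing_depth=20_000,
            correlation_blocks=[
                (list(range(0, 8)), 0.7),
                (list(range(8, 16)), 0.7),
                (list(range(16, 19)), -0.5),
            ],
            enterotype_components=[
                (0.6, [100, 101, 102], 15.0),
                (0.4, [105, 106, 107], 15.0),
            ],
            effect_taxa=[
                (30, 2.0, 0.0),
                (31, -2.0, 0.0),
                (32, 0.0, 1.0),
                (33, 0.0, -1.0),
                (34, 1.5, 0.8),
            ],
            sex_effect=1.0,
            batch_effects=(0.0, 0.8, -0.5),
            residual_sd=1.0,
            zero_inflation=0.05,
            seed=seed,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth aligned with the generated table."""

    enterotype_labels: np.ndarray      # per-sample component index
    block_labels: np.ndarray           # per-taxon block index, -1 = none
    true_effects: np.ndarray           # n_taxa x 2 (beta1, beta2)
    basis_correlation: np.ndarray      # n_taxa x n_taxa
    repair_distance: float             # Frobenius distance of the PSD repair


def _nearest_psd(corr: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue clipping at 0 then re-normalization to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= -1e-12:
        return corr, 0.0
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(repaired), 1e-12, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2
    return repaired, float(np.linalg.norm(repaired - corr, "fro"))


def build_basis_correlation(config: SimulationConfig) -> tuple[np.ndarray, float]:
    """Block-structured basis correlation matrix and its PSD-repair distance.

    Taxa outside every block are independent. The assembled matrix is
    projected to the nearest positive semi-definite correlation matrix
    (eigenvalue clipping + diagonal re-normalization); the Frobenius
    distance moved is returned so callers can tell whether the requested
    blocks were realisable as stated.
    """
    config.validate()
    corr = np.eye(config.n_taxa)
    for members, rho in config.correlation_blocks:
        for a in members:
            for b in members:
                if a != b:
                    corr[a, b] = rho
    return _nearest_psd(corr)


def block_label_vector(config: SimulationConfig) -> np.ndarray:
    labels = np.full(config.n_taxa, -1, dtype=int)
    for b, (members, _) in enumerate(config.correlation_blocks):
        labels[members] = b
    return labels


def simulate_counts(config: SimulationConfig) -> tuple[OtuTable, SyntheticTruth]:
    """Draw the OTU count table and its ground truth.

    Per sample: draw an enterotype component; draw correlated log-normal
    basis abundances (component shifts the log-mean of its dominant taxa by
    ``log(fold_change)``); close to a composition; multinomial at
    ``sequencing_depth``; apply per-taxon dropout.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    n, d = config.n_samples, config.n_taxa

    corr, repair = build_basis_correlation(config)
    # eigh-based square root: robust to the PSD-boundary blocks cholesky rejects
    w, v = np.linalg.eigh(corr)
    chol_like = v * np.sqrt(np.clip(w, 0.0, None))

    base_mu = rng.normal(0.0, config.log_mean_sd, size=d)
    # enterotype drivers are abundant genera: pin their baseline to the
    # upper tail so the dominance fold acts on an already-common taxon
    for _, dominants, _ in config.enterotype_components:
        base_mu[dominants] = 1.5 * config.log_mean_sd

    if config.enterotype_components:
        weights = np.array([c[0] for c in config.enterotype_components])
        components = rng.choice(len(weights), size=n, p=weights)
    else:
        components = np.zeros(n, dtype=int)

    mu = np.tile(base_mu, (n, 1))
    for k, (_, dominants, fold) in enumerate(config.enterotype_components):
        mu[np.ix_(components == k, dominants)] += np.log(fold)

    z = rng.standard_normal((n, d)) @ chol_like.T
    log_abundance = mu + config.log_sd * z
    basis = np.exp(log_abundance)
    comp = basis / basis.sum(axis=1, keepdims=True)

    counts = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(config.sequencing_depth, comp[i])

    zi = np.broadcast_to(np.asarray(config.zero_inflation, dtype=float), (d,))
    if zi.any():
        drop = rng.random((n, d)) < zi[None, :]
        counts[drop] = 0

    table = OtuTable(
        pd.DataFrame(counts, index=config.sample_ids(), columns=config.taxon_ids()),
        kind="counts",
    )
    effects = np.zeros((d, 2))
    for t, b1, b2 in config.effect_taxa:
        effects[t] = (b1, b2)
    truth = SyntheticTruth(
        enterotype_labels=components,
        block_labels=block_label_vector(config),
        true_effects=effects,
        basis_correlation=corr,
        repair_distance=repair,
    )
    return table, truth


def simulate_phenotype(
    table: OtuTable, truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Generate sample metadata with an LMP phenotype driven by the table.

    phenotype = intercept + sex effect + batch effect
                + sum_t [beta1(t) * presence(t) + beta2(t) * z(t)]
                + Normal(0, residual_sd)

    where z(t) is the log10 relative abundance of taxon t standardized over
    its detected samples (zero where undetected) — the same quantity the
    two-part scan regresses on. Sex and batch are assigned round-robin after
    a seeded shuffle. Backfat and loin-muscle area are reported such that
    the carcass-grading formula reproduces the simulated LMP exactly.
    """
    if table.n_samples != len(truth.enterotype_labels):
        raise ConfigError("table and truth are not aligned")
    if table.n_taxa != truth.true_effects.shape[0]:
        raise ConfigError("effect vector does not match the table's taxa")
    rng = np.random.default_rng([config.seed, 2])
    n = table.n_samples
    counts = table.values.astype(float)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        raise ConfigError("sample with zero total count; cannot derive abundances")
    rel = counts / row_sums[:, None]
    presence = counts > 0

    order = rng.permutation(n)
    sex = np.empty(n, dtype=object)
    sex[order] = np.where(np.arange(n) % 2 == 0, "M", "F")
    n_batches = len(config.batch_effects)
    batch = np.empty(n, dtype=int)
    batch[order] = np.arange(n) % n_batches

    y = np.full(n, config.phenotype_intercept, dtype=float)
    y += np.where(sex == "M", config.sex_effect, 0.0)
    y += np.asarray(config.batch_effects)[batch]

    for t in range(table.n_taxa):
        b1, b2 = truth.true_effects[t]
        if b1 == 0.0 and b2 == 0.0:
            continue
        det = presence[:, t]
        y += b1 * det
        if b2 != 0.0 and det.sum() >= 3:
            x = np.log10(rel[det, t])
            sd = x.std(ddof=1)
            if sd > 0:
                z = np.zeros(n)
                z[det] = (x - x.mean()) / sd
                y += b2 * z
    y += rng.normal(0.0, config.residual_sd, size=n)

    # invert the grading formula so compute_lmp(backfat, lma) == y exactly
    lma = rng.normal(42.0, 2.5, size=n).clip(min=30.0)
    backfat = (LMP_INTERCEPT + LMP_LMA_COEF * lma - y / LMP_SCALE) / (-LMP_BF_COEF)
    low = backfat < 0.5
    if low.any():  # keep measurements physical; adjust area instead
        lma[low] += (0.5 - backfat[low]) * (-LMP_BF_COEF) / LMP_LMA_COEF
        backfat[low] = 0.5

    return pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "sex": sex,
            "batch": [f"B{b + 1}" for b in batch],
            "backfat_mm": backfat,
            "lma_cm2": lma,
            "lmp": y,
        }
    ).set_index("sample_id")


def make_taxonomy(config: SimulationConfig) -> TaxonomyMap:
    """Taxonomy for the synthetic taxa.

    Each enterotype component's dominant taxa share one genus (so dominance
    is visible at genus level); everything else gets its own genus.
    """
    genus_names = ["Prevotella", "Treponema", "Lactobacillus", "Ruminococcus"]
    genus = [f"genus_{i + 1}" for i in range(config.n_taxa)]
    for k, (_, dominants, _) in enumerate(config.enterotype_components):
        name = genus_names[k] if k < len(genus_names) else f"dominant_{k + 1}"
        for t in dominants:
            genus[t] = name
    df = pd.DataFrame(
        {
            "genus": genus,
            "species": [f"{g} sp{i + 1}" for i, g in enumerate(genus)],
        },
        index=pd.Index(config.taxon_ids(), name="taxon_id"),
    )
    return TaxonomyMap(df)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[OtuTable, TaxonomyMap, pd.DataFrame, SyntheticTruth]:
    """Counts + taxonomy + metadata + truth in one call."""
    table, truth = simulate_counts(config)
    metadata = simulate_phenotype(table, truth, config)
    taxonomy = make_taxonomy(config)
    return table, taxonomy, metadata, truth


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the standard pipeline inputs (all TSV) plus the truth bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, taxonomy, metadata, truth = simulate_dataset(config)
    paths = {
        "otu_table": outdir / "otu_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth_enterotypes": outdir / "truth_enterotypes.tsv",
        "truth_taxa": outdir / "truth_taxa.tsv",
    }
    write_otu_table(table, paths["otu_table"])
    write_taxonomy(taxonomy, paths["taxonomy"])
    metadata.to_csv(paths["metadata"], sep="\t")
    pd.DataFrame(
        {"sample_id": table.sample_ids, "enterotype": truth.enterotype_labels}
    ).to_csv(paths["truth_enterotypes"], sep="\t", index=False)
    pd.DataFrame(
        {
            "taxon_id": table.taxon_ids,
            "block": truth.block_labels,
            "beta1": truth.true_effects[:, 0],
            "beta2": truth.true_effects[:, 1],
        }
    ).to_csv(paths["truth_taxa"], sep="\t", index=False)
    return paths
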