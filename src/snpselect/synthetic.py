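"""Case/control genotype simulation with known causal structure.

Genotypes are drawn per SNP under Hardy-Weinberg equilibrium with a minor
allele frequency sampled uniformly from a configurable range. Disease status
follows a logistic liability model: main-effect causal SNPs contribute
``log(OR) * genotype`` on the logit scale, and each planted epistatic pair
contributes ``logit(penetrance[g_a][g_b]) - logit(baseline)`` so that
pure-epistasis configurations (all odds ratios 1) reduce exactly to the
penetrance table. Case and control quotas are filled by rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import GenotypeMatrix


class SimulationError(RuntimeError):
    """Raised when the case/control quotas cannot be filled."""


#: Rejection-sampling cap: give up after this multiple of the target cohort size.
REJECTION_CAP_FACTOR = 1000


@dataclass
class SimulationConfig:
    """Parameters of one simulated case/control cohort.

    ``causal_snps`` is a list of ``(snp_index, odds_ratio)`` main effects;
    ``epistatic_pairs`` is a list of ``(index_a, index_b, penetrance)`` where
    ``penetrance`` is a 3x3 table of P(case | g_a, g_b). ``ld_block_size`` > 1
    turns on a simple block-correlation structure: within each consecutive
    block, a SNP copies its left neighbour's genotype and is re-drawn from
    HWE with probability ``ld_flip_prob`` per subject.
    """

    n_cases: int
    n_controls: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    epistatic_pairs: list[tuple[int, int, np.ndarray]] = field(default_factory=list)
    baseline_prevalence: float = 0.5
    seed: int = 0
    ld_block_size: int = 1
    ld_flip_prob: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")
        used: set[int] = set()
        for j, odds in self.causal_snps:
            if not 0 <= j < self.n_snps:
                raise ValueError(f"causal SNP index {j} out of range")
            if odds <= 0:
                raise ValueError("odds ratios must be positive")
            used.add(j)
        for a, b, table in self.epistatic_pairs:
            tab = np.asarray(table, dtype=float)
            if tab.shape != (3, 3) or tab.min() < 0 or tab.max() > 1:
                raise ValueError("penetrance table must be 3x3 with entries in [0,1]")
            for j in (a, b):
                if not 0 <= j < self.n_snps:
                    raise ValueError(f"epistatic index {j} out of range")
                if j in used:
                    raise ValueError(f"index {j} used by more than one causal term")
                used.add(j)


def hw_genotype_probs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2) for MAF q."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    p = 1.0 - maf
    return (p * p, 2.0 * maf * p, maf * maf)


def _logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-p)


def _draw_genotypes(rng: np.random.Generator, mafs: np.ndarray, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Draw an n x d genotype block under HWE, optionally with LD blocks."""
    d = mafs.size
    u = rng.random((n, d))
    hom_ref = (1.0 - mafs) ** 2
    het = hom_ref + 2.0 * mafs * (1.0 - mafs)
    geno = np.where(u < hom_ref, 0.0, np.where(u < het, 1.0, 2.0))
    if cfg.ld_block_size > 1:
        for j in range(d):
            if j % cfg.ld_block_size == 0:
                continue
            keep = rng.random(n) >= cfg.ld_flip_prob
            geno[keep, j] = geno[keep, j - 1]
    return geno


def _case_probability(geno: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    logit_p = np.full(geno.shape[0], float(_logit(cfg.baseline_prevalence)))
    for j, odds in cfg.causal_snps:
        logit_p = logit_p + np.log(odds) * geno[:, j]
    for a, b, table in cfg.epistatic_pairs:
        tab = np.clip(np.asarray(table, dtype=float), 1e-12, 1.0 - 1e-12)
        cell = _logit(tab)[geno[:, a].astype(int), geno[:, b].astype(int)]
        logit_p = logit_p + cell - _logit(cfg.baseline_prevalence)
    return 1.0 / (1.0 + np.exp(-logit_p))


def simulate_dataset(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate genotypes and labels until the case/control quotas are met.

    Deterministic given ``config.seed``. Raises :class:`SimulationError` if
    the quotas cannot be filled within ``REJECTION_CAP_FACTOR`` times the
    cohort size (e.g. an all-zero penetrance table with no controls wanted).
    """
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_snps)
    target = config.n_cases + config.n_controls
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    drawn = 0
    cap = REJECTION_CAP_FACTOR * target
    batch = max(256, target)
    while (sum(len(c) for c in cases) < config.n_cases
           or sum(len(c) for c in controls) < config.n_controls):
        if drawn >= cap:
            raise SimulationError(
                f"could not fill quotas after {drawn} draws; "
                "check penetrance/odds-ratio configuration"
            )
        geno = _draw_genotypes(rng, mafs, batch, config)
        p = _case_probability(geno, config)
        is_case = rng.random(batch) < p
        cases.append(geno[is_case])
        controls.append(geno[~is_case])
        drawn += batch

    case_g = np.concatenate(cases)[: config.n_cases]
    ctrl_g = np.concatenate(controls)[: config.n_controls]
    values = np.concatenate([case_g, ctrl_g])
    labels = np.concatenate(
        [np.ones(config.n_cases, dtype=int), -np.ones(config.n_controls, dtype=int)]
    )
    # interleave deterministically so class is not confounded with row order
    order = rng.permutation(target)
    values = values[order]
    labels = labels[order]
    snp_ids = [f"X{j + 1}" for j in range(config.n_snps)]
    subject_ids = [f"s{i + 1}" for i in range(target)]
    return GenotypeMatrix(values, snp_ids, subject_ids, labels)


def xor_penetrance(high: float = 0.8, low: float = 0.2) -> np.ndarray:
    """Penetrance table with elevated risk iff exactly one locus is heterozygous.

    This pattern has (approximately) no marginal effect at either locus and is
    the canonical two-locus interaction that single-SNP methods miss.
    """
    tab = np.full((3, 3), low)
    for a in range(3):
        for b in range(3):
            if (a == 1) != (b == 1):
                tab[a, b] = high
    return tab
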