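"""Synthetic genotypes, haplotypes and allelic counts, and the power study.

Allelic expression of ``n_subjects`` subjects is generated directly from the
HPMM: a heterozygote contributes two allelic counts (offset ``l/2`` each), a
homozygote one total count (offset ``l``), with a subject-level random
intercept of variance ``var_b`` and an observation-level random effect of
variance ``var_eps``.  Genotypes are drawn under Hardy-Weinberg equilibrium;
two-locus haplotypes come from a four-haplotype table parameterised by the
two minor-allele frequencies and the haplotype correlation ``ld_r``.

The study design defaults mirror the comparison of the HPMM (all subjects),
the HPMM restricted to heterozygotes, and beta-binomial regression:
500 subjects, Var(b) = 1, Var(eps) = 0.5, effect sizes 0 to 0.3 and minor
allele frequencies 0.1 to 0.4, evaluated at the 5% level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hpmm import fit_betabin, fit_hpmm, pairs_from_observations

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_haplotypes",
    "simulate_counts",
    "simulate_ase_dataset",
    "run_power_study",
]

DEFAULT_BETA_GRID = (0.0, 0.1, 0.2, 0.3)
DEFAULT_MAF_GRID = (0.1, 0.2, 0.3, 0.4)


@dataclass
class SimConfig:
    """Parameters of one simulated allelic-expression dataset.

    ``mu`` defaults to the baseline log-rate that gives an expected count of
    ``mean_count`` per allelic observation (offset ``library_size / 2``)
    after averaging over the lognormal random effects.
    """

    n_subjects: int = 500
    maf: float = 0.4
    beta: float = 0.0
    var_b: float = 1.0
    var_eps: float = 0.5
    mu: float | None = None
    library_size: float = 1e6
    mean_count: float = 50.0
    ld_r: float = 0.0
    n_replicates: int = 2000
    alpha: float = 0.05
    seed: int = 0

    def resolved_mu(self) -> float:
        if self.mu is not None:
            return self.mu
        return (
            math.log(self.mean_count / (self.library_size / 2.0))
            - 0.5 * (self.var_b + self.var_eps)
        )


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Minor-allele dosages (0/1/2) under Hardy-Weinberg equilibrium."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    probs = [(1.0 - maf) ** 2, 2.0 * maf * (1.0 - maf), maf**2]
    return rng.choice(3, size=n, p=probs)


def haplotype_frequencies(maf_gwas: float, maf_exonic: float, ld_r: float) -> dict[str, float]:
    """Four-haplotype table for minor alleles a, b with correlation ``ld_r``.

    ``P(ab) = p_a * p_b + r * sqrt(p_a(1-p_a) p_b(1-p_b))``; raises when the
    requested correlation is infeasible for the allele frequencies, naming
    the feasible range.
    """
    pa, pb = maf_gwas, maf_exonic
    denom = math.sqrt(pa * (1 - pa) * pb * (1 - pb))
    d = ld_r * denom
    freqs = {
        "ab": pa * pb + d,
        "aB": pa * (1 - pb) - d,
        "Ab": (1 - pa) * pb - d,
        "AB": (1 - pa) * (1 - pb) + d,
    }
    if any(f < -1e-12 or f > 1 + 1e-12 for f in freqs.values()):
        lo = max(-pa * pb, -(1 - pa) * (1 - pb)) / denom
        hi = min(pa * (1 - pb), (1 - pa) * pb) / denom
        raise ValueError(
            f"ld_r={ld_r} infeasible for MAFs ({pa}, {pb}); "
            f"feasible range is [{lo:.4f}, {hi:.4f}]"
        )
    return {k: min(max(v, 0.0), 1.0) for k, v in freqs.items()}


def simulate_haplotypes(
    n: int,
    maf_gwas: float,
    maf_exonic: float,
    ld_r: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phased two-locus genotypes for ``n`` subjects.

    Returns one row per subject with columns ``g1, e1, g2, e2``: minor-allele
    indicators at the GWAS (g) and exonic (e) locus on haplotypes 1 and 2.
    """
    freqs = haplotype_frequencies(maf_gwas, maf_exonic, ld_r)
    haps = ["AB", "Ab", "aB", "ab"]
    p = np.array([freqs[h] for h in haps])
    p = p / p.sum()
    draws = rng.choice(4, size=2 * n, p=p)
    g = (draws >= 2).astype(int)  # carries minor GWAS allele a
    e = (draws % 2).astype(int)  # carries minor exonic allele b
    return pd.DataFrame(
        {
            "g1": g[:n],
            "e1": e[:n],
            "g2": g[n:],
            "e2": e[n:],
        }
    )


def _design_skeleton(dosage: np.ndarray, library_size: float) -> pd.DataFrame:
    """Exonic-mode design rows for minor-allele dosages under effect allele A.

    X = 1 for the major (effect) allele pattern, 0 for the minor; a
    heterozygote is split into the paired patterns (A, a).
    """
    rows = []
    for i, d in enumerate(dosage):
        sid = f"S{i:04d}"
        if d == 1:
            rows.append((sid, "A", 1.0, library_size / 2.0))
            rows.append((sid, "a", 0.0, library_size / 2.0))
        elif d == 0:
            rows.append((sid, "AA", 1.0, library_size))
        else:
            rows.append((sid, "aa", 0.0, library_size))
    return pd.DataFrame(rows, columns=["subject_id", "pattern", "X", "K"])


def simulate_counts(
    skeleton: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw Poisson counts on a design skeleton from the HPMM.

    ``b_i ~ N(0, var_b)`` per subject, ``eps_ij ~ N(0, var_eps)`` per row,
    ``y ~ Poisson(exp(mu + X beta + b + eps) * K)``.
    """
    obs = skeleton.copy()
    mu = config.resolved_mu()
    subjects, codes = np.unique(obs["subject_id"].to_numpy(), return_inverse=True)
    b = rng.normal(0.0, math.sqrt(config.var_b), size=len(subjects))[codes]
    eps = rng.normal(0.0, math.sqrt(config.var_eps), size=len(obs))
    rate = np.exp(mu + obs["X"].to_numpy() * config.beta + b + eps) * obs["K"].to_numpy()
    obs["y"] = rng.poisson(rate)
    return obs


def simulate_ase_dataset(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One exonic-mode allelic-expression dataset drawn from the HPMM."""
    dosage = simulate_genotypes(config.n_subjects, config.maf, rng)
    skeleton = _design_skeleton(dosage, config.library_size)
    return simulate_counts(skeleton, config, rng)


def _het_subset(obs: pd.DataFrame) -> pd.DataFrame:
    counts = obs.groupby("subject_id")["y"].transform("size")
    return obs[counts == 2]


def _fit_method(obs: pd.DataFrame, method: str):
    """Return (p_value, converged) for one method on one dataset."""
    if method == "hpmm_all":
        fit = fit_hpmm(obs, refine=False)
        return fit.p_value, fit.converged
    if method == "hpmm_het":
        het = _het_subset(obs)
        fit = fit_hpmm(het, refine=False)
        return fit.p_value, fit.converged
    if method == "betabin":
        y_eff, n_tot = pairs_from_observations(_het_subset(obs))
        fit = fit_betabin(y_eff, n_tot)
        return fit.p_value, fit.converged
    raise ValueError(f"unknown method {method!r}")


def run_power_study(
    config: SimConfig | None = None,
    betas=DEFAULT_BETA_GRID,
    mafs=DEFAULT_MAF_GRID,
    methods=("hpmm_all", "hpmm_het", "betabin"),
    n_replicates: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical rejection rate of each method over a (beta, MAF) grid.

    All methods are evaluated on the same replicate datasets.  Replicates in
    which a method failed to converge are excluded from that method's
    denominator (their number is reported in ``n_failed``).  Returns one row
    per (beta, maf, method) with the rejection rate and its binomial
    Monte-Carlo standard error.
    """
    cfg = config or SimConfig()
    if n_replicates is not None:
        cfg = replace(cfg, n_replicates=n_replicates)
    if seed is not None:
        cfg = replace(cfg, seed=seed)

    cells = [(b, m) for b in betas for m in mafs]
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cells))
    rows = []
    for (beta, maf), ss in zip(cells, streams):
        cell_cfg = replace(cfg, beta=beta, maf=maf)
        rng = np.random.default_rng(ss)
        rejected = {m: 0 for m in methods}
        n_ok = {m: 0 for m in methods}
        for _ in range(cell_cfg.n_replicates):
            obs = simulate_ase_dataset(cell_cfg, rng)
            for m in methods:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p, ok = _fit_method(obs, m)
                if not ok or p is None or not np.isfinite(p):
                    continue
                n_ok[m] += 1
                rejected[m] += p < cell_cfg.alpha
        for m in methods:
            rate = rejected[m] / n_ok[m] if n_ok[m] else float("nan")
            mc_se = (
                math.sqrt(rate * (1.0 - rate) / n_ok[m]) if n_ok[m] else float("nan")
            )
            rows.append(
                {
                    "beta": beta,
                    "maf": maf,
                    "method": m,
                    "n_replicates": cell_cfg.n_replicates,
                    "n_converged": n_ok[m],
                    "n_failed": cell_cfg.n_replicates - n_ok[m],
                    "rejection_rate": rate,
                    "mc_se": mc_se,
                }
            )
    return pd.DataFrame(rows)
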