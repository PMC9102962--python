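"""Multi-environment trial analysis: BLUEs, variance components, H2.

The plot model is

    y_ikmb = mu + g_i + tau_k + (g tau)_ik + delta_km + beta_mb + e_ikmb

with genotype g_i, environment tau_k, genotype-by-environment
interaction, replicate nested in environment, block nested in
replicate, and plot residual.  For BLUEs the genotype is fixed and
every other term random; for broad-sense heritability all terms are
random and

    H2 = sigma_g^2 / (sigma_g^2 + sigma_gxe^2 / n + sigma_e^2 / (n r))

on an entry-mean basis with n environments and r replicates.
All fits use REML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from ._reml import indicator_matrix, reml_sparse

REQUIRED_COLUMNS = ("genotype", "environment", "replicate", "block", "value")


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_gxe: float
    sigma2_eps: float
    n_environments: int
    n_replicates: int

    @property
    def H2(self) -> float:
        return estimate_heritability(self)


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype records missing columns: {missing}")
    if not np.isfinite(records["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite phenotype values")
    keys = records[["genotype", "environment", "replicate", "block"]]
    if keys.duplicated().any():
        raise ValueError("duplicated (genotype, environment, replicate, block) keys")
    return records


def _random_terms(records: pd.DataFrame, include_genotype: bool):
    """Sparse indicator blocks for the model's random strata, dropping
    degenerate single-level terms."""
    env = records["environment"].astype(str)
    rep = env + ":" + records["replicate"].astype(str)
    blk = rep + ":" + records["block"].astype(str)
    gxe = records["genotype"].astype(str) + ":" + env
    candidates = []
    if include_genotype:
        candidates.append(("genotype", records["genotype"].astype(str)))
    candidates += [("environment", env), ("gxe", gxe),
                   ("replicate", rep), ("block", blk)]
    terms = []
    # compare partitions (not labels) so e.g. GxE collapsing onto genotype
    # in a single-environment design is dropped rather than made collinear
    seen = set()
    if not include_genotype:
        seen.add(tuple(pd.factorize(records["genotype"].astype(str))[0]))
    for name, labels in candidates:
        Z, levels = indicator_matrix(labels)
        key = tuple(pd.factorize(labels)[0])
        if len(levels) < 2 or key in seen:
            continue
        seen.add(key)
        terms.append((name, Z))
    return terms


def fit_blues(records: pd.DataFrame) -> pd.Series:
    """Genotype BLUEs (mu + g_i) from a joint multi-environment fit.

    Genotype enters as fixed dummies without an intercept so the
    estimates carry the overall mean; environment, GxE, replicate and
    block are zero-mean normal random effects estimated by REML.  Falls
    back to per-genotype means (with a warning) when the design leaves
    no residual degrees of freedom.
    """
    records = _validate(records)
    g_labels = records["genotype"].astype(str)
    genotypes = np.unique(g_labels)
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    y = records["value"].to_numpy(dtype=float)
    Xs, levels = indicator_matrix(g_labels)
    counts = records.groupby("genotype").size()
    if len(records) <= len(genotypes) or (counts < 2).all():
        warnings.warn(
            "design not identifiable beyond genotype means; returning means",
            stacklevel=2,
        )
        return records.groupby("genotype")["value"].mean().rename("blue")
    X = np.asarray(Xs.todense(), dtype=float)
    terms = _random_terms(records, include_genotype=False)
    if not terms:
        return records.groupby("genotype")["value"].mean().rename("blue")
    fit = reml_sparse(y, X, terms)
    return pd.Series(fit.fixed_effects, index=levels, name="blue")


def fit_variance_components(records: pd.DataFrame) -> VarianceComponents:
    """All-random-effects fit (intercept only fixed) for heritability."""
    records = _validate(records)
    y = records["value"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    terms = _random_terms(records, include_genotype=True)
    fit = reml_sparse(y, X, terms)
    n_env = records["environment"].nunique()
    n_rep = records.groupby("environment")["replicate"].nunique().max()
    return VarianceComponents(
        sigma2_g=fit.variances.get("genotype", 0.0),
        sigma2_gxe=fit.variances.get("gxe", 0.0),
        sigma2_eps=fit.variances["residual"],
        n_environments=int(n_env),
        n_replicates=int(n_rep),
    )


def estimate_heritability(components: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability from variance components."""
    if components.n_environments < 1 or components.n_replicates < 1:
        raise ValueError("need n, r >= 1")
    n, r = components.n_environments, components.n_replicates
    denom = (
        components.sigma2_g
        + components.sigma2_gxe / n
        + components.sigma2_eps / (n * r)
    )
    if denom == 0:
        raise ValueError("all variance components are zero; H2 undefined")
    h2 = components.sigma2_g / denom
    return float(min(max(h2, 0.0), 1.0))


def describe_population(values) -> dict:
    """Mean, sample SD, N, CV% and range, as in a trial summary table."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    out = {
        "mean": mean,
        "sd": sd,
        "n": int(v.size),
        "cv_pct": 100.0 * sd / mean if mean != 0 else np.nan,
        "cv_defined": mean != 0,
        "range": (float(v.min()), float(v.max())),
    }
    return out


def environment_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of per-genotype environment means.

    Pairs with fewer than three shared genotypes are omitted.
    """
    records = _validate(records)
    wide = records.pivot_table(
        index="genotype", columns="environment", values="value", aggfunc="mean"
    )
    envs = list(wide.columns)
    if len(envs) < 2:
        raise ValueError("need at least two environments")
    rows = []
    for i, e1 in enumerate(envs):
        for e2 in envs[i + 1 :]:
            pair = wide[[e1, e2]].dropna()
            if len(pair) < 3:
                continue
            r, p = scipy.stats.pearsonr(pair[e1], pair[e2])
            rows.append({"env1": e1, "env2": e2, "r": float(r),
                         "p_value": float(p), "n_shared": len(pair)})
    return pd.DataFrame(rows, columns=["env1", "env2", "r", "p_value", "n_shared"])
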