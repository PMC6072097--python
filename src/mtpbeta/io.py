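"""Abundance/metadata tables, the per-OTU batch pipeline, and utilities.

The batch pipeline is the applied workflow: for each OTU build a
two-part dataset from its relative-abundance row and the shared design
matrix, test the covariate of interest with the requested methods,
Bonferroni-adjust within each method across the OTUs it actually
tested, and summarize per-method significant counts plus the
cross-method agreement pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit as _expit
from scipy.stats import beta as beta_dist

from .estimation import FitConfig, ModelFit, fit_ctp, fit_mtp
from .inference import (bonferroni_adjust, comparison_tests, lrt_ctp_effect,
                        lrt_mtp_effect, mtp_effect)
from .model import TwoPartDataset

logger = logging.getLogger(__name__)

__all__ = ["AbundanceTable", "OTUResultRow", "read_abundance_table",
           "write_abundance_table", "read_metadata", "batch_analyze",
           "predicted_density", "synthetic_skin_table"]

TWO_PART_METHODS = ("LRT-MTP", "LRT-CTP")
COMPARISON_METHODS = ("T-test", "Wilcoxon")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Relative abundances, rows = OTUs, columns = samples."""

    values: np.ndarray
    otu_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    taxonomy: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a matrix")
        self.otu_ids = tuple(str(o) for o in self.otu_ids)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        if v.shape != (len(self.otu_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match otu/sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("otu_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if np.any(v < 0) or np.any(v >= 1):
            i, j = np.argwhere((v < 0) | (v >= 1))[0]
            raise ValueError(
                f"abundance outside [0, 1) at OTU {self.otu_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}: {v[i, j]}")
        if self.taxonomy is not None:
            self.taxonomy = tuple(str(t) for t in self.taxonomy)
            if len(self.taxonomy) != len(self.otu_ids):
                raise ValueError("taxonomy length must match otu_ids")
        colsums = v.sum(axis=0)
        if np.any(colsums > 1.0 + 1e-6):
            j = int(np.argmax(colsums))
            logger.warning(
                "sample %s column sum %.6f exceeds 1 (composition should "
                "sum to at most 1)", self.sample_ids[j], colsums[j])
        self.values = v

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def zero_fractions(self) -> pd.Series:
        return pd.Series((self.values == 0).mean(axis=1),
                         index=list(self.otu_ids), name="zero_fraction")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.otu_ids),
                            columns=list(self.sample_ids))


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_abundance_table(path,
                         orientation: Literal["otus_in_rows",
                                              "samples_in_rows"] = "otus_in_rows",
                         sep: str | None = None) -> AbundanceTable:
    """Read a CSV/TSV abundance table (first column = row labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0,
                     float_precision="round_trip")
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "otus_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    non_numeric = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric cell in column {col!r}, row {bad.index[0]!r}")
        df = df.apply(pd.to_numeric)
    return AbundanceTable(df.to_numpy(float), tuple(df.index.astype(str)),
                          tuple(df.columns.astype(str)))


def write_abundance_table(table: AbundanceTable, path,
                          sep: str | None = None) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path, sep),
                            float_format="%.17g")


def read_metadata(path, covariate_spec, sample_ids: Sequence[str],
                  sep: str | None = None) -> pd.DataFrame:
    """Build a design matrix from a metadata table keyed by sample id.

    ``covariate_spec`` is a sequence of column names, or a mapping
    column -> reference level for categorical columns (the reference
    level is coded 0).  The returned frame has an ``intercept`` first
    column and rows ordered to ``sample_ids`` regardless of file order.
    """
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    meta.index = meta.index.astype(str)
    sample_ids = [str(s) for s in sample_ids]
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:10]}")
    meta = meta.loc[sample_ids]
    if isinstance(covariate_spec, Mapping):
        spec = dict(covariate_spec)
    else:
        spec = {c: None for c in covariate_spec}
    cols = {"intercept": np.ones(len(sample_ids))}
    for name, ref in spec.items():
        if name not in meta.columns:
            raise ValueError(f"covariate {name!r} not in metadata")
        col = meta[name]
        if np.issubdtype(col.dtype, np.number) and ref is None:
            vals = col.to_numpy(float)
            cols[name] = vals
        else:
            levels = sorted(col.astype(str).unique())
            ref = str(ref) if ref is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in "
                                 f"column {name!r} (levels: {levels})")
            for lvl in levels:
                if lvl == ref:
                    continue
                cols[f"{name}[{lvl}]"] = (col.astype(str) == lvl).to_numpy(float)
        added = [k for k in cols if k != "intercept"]
        for k in added:
            if np.ptp(cols[k]) == 0:
                raise ValueError(f"covariate {k!r} is constant")
    design = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    return design


# ---------------------------------------------------------------------------
# batch differential-abundance analysis
# ---------------------------------------------------------------------------

@dataclass
class OTUResultRow:
    otu_id: str
    taxonomy: str | None
    zero_fraction: float
    p_values: dict[str, float] = field(default_factory=dict)
    adjusted_p: dict[str, float] = field(default_factory=dict)
    mtp_estimate: float = np.nan
    mtp_se: float = np.nan
    converged: dict[str, bool] = field(default_factory=dict)
    skip_reason: dict[str, str] = field(default_factory=dict)


@dataclass
class BatchResult:
    rows: list[OTUResultRow]
    methods: tuple[str, ...]
    alpha_level: float
    significant_counts: dict[str, int]
    agreement: pd.DataFrame          # per-OTU 0/1 significance indicators
    pattern_counts: pd.Series        # Venn-style counts per method pattern

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"otu_id": r.otu_id, "taxonomy": r.taxonomy,
                   "zero_fraction": r.zero_fraction,
                   "mtp_estimate": r.mtp_estimate, "mtp_se": r.mtp_se}
            for m in self.methods:
                rec[f"p[{m}]"] = r.p_values.get(m, np.nan)
                rec[f"p_adj[{m}]"] = r.adjusted_p.get(m, np.nan)
                rec[f"converged[{m}]"] = r.converged.get(m, False)
                rec[f"skip[{m}]"] = r.skip_reason.get(m, "")
            recs.append(rec)
        return pd.DataFrame(recs)

    def summary(self) -> str:
        lines = [f"batch analysis: {len(self.rows)} OTUs, "
                 f"level {self.alpha_level} (Bonferroni-adjusted)"]
        for m in self.methods:
            lines.append(f"  {m:<8s}: {self.significant_counts[m]} significant")
        lines.append("method-pattern counts (1 = significant):")
        lines.append(self.pattern_counts.to_string())
        return "\n".join(lines)


def batch_analyze(table: AbundanceTable, design: pd.DataFrame,
                  methods: Sequence[str] = TWO_PART_METHODS + COMPARISON_METHODS,
                  alpha_level: float = 0.05,
                  covariate: int | str = 1,
                  adjust: Literal["bonferroni", "none"] = "bonferroni",
                  config: FitConfig | None = None) -> BatchResult:
    """Per-OTU differential-abundance testing across the whole table.

    OTUs that are all-zero or all-positive cannot support a two-part
    fit; they are skipped for the likelihood methods with a recorded
    reason (comparison tests still run).  Convergence failures are
    recorded per OTU, never aborting the batch.  Bonferroni's m is the
    number of OTUs actually tested by each method.
    """
    methods = tuple(methods)
    known = TWO_PART_METHODS + COMPARISON_METHODS
    unknown = set(methods) - set(known)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if list(design.index) != list(table.sample_ids):
        design = design.loc[list(table.sample_ids)]
    X = design.to_numpy(float)
    j = (int(covariate) if not isinstance(covariate, str)
         else int(design.columns.get_loc(covariate)))
    config = config or FitConfig()
    rows: list[OTUResultRow] = []
    for i, otu in enumerate(table.otu_ids):
        y = table.values[i]
        row = OTUResultRow(
            otu_id=otu,
            taxonomy=table.taxonomy[i] if table.taxonomy else None,
            zero_fraction=float(np.mean(y == 0)))
        n_pos = int(np.sum(y > 0))
        degenerate = ("all outcomes zero" if n_pos == 0 else
                      "no zero outcomes" if n_pos == len(y) else None)
        data = None
        if degenerate is None:
            data = TwoPartDataset(y, X, tuple(design.columns))
        for m in methods:
            if m in TWO_PART_METHODS:
                if degenerate is not None:
                    row.skip_reason[m] = degenerate
                    logger.info("OTU %s: %s skipped (%s)", otu, m, degenerate)
                    continue
                try:
                    if m == "LRT-MTP":
                        res = lrt_mtp_effect(data, j, config)
                        eff = mtp_effect(res.detail["full_fit"], j)
                        row.mtp_estimate = eff.estimate
                        row.mtp_se = eff.se
                    else:
                        res = lrt_ctp_effect(data, j, config)
                    row.p_values[m] = res.p_value
                    row.converged[m] = True
                except (RuntimeError, ValueError) as exc:
                    row.converged[m] = False
                    row.skip_reason[m] = f"fit failed: {exc}"
                    logger.warning("OTU %s: %s failed (%s)", otu, m, exc)
            else:
                try:
                    ydata = data if data is not None else None
                    if ydata is None:
                        # comparison tests tolerate degenerate zero patterns
                        ydata = TwoPartDataset(y, X, tuple(design.columns))
                    t, w = comparison_tests(ydata, j)
                    row.p_values["T-test"] = t.p_value
                    row.p_values["Wilcoxon"] = w.p_value
                except ValueError as exc:
                    row.skip_reason[m] = str(exc)
        rows.append(row)

    for m in methods:
        tested = [r for r in rows if m in r.p_values]
        if tested:
            adj = (bonferroni_adjust([r.p_values[m] for r in tested])
                   if adjust == "bonferroni"
                   else np.asarray([r.p_values[m] for r in tested]))
            for r, a in zip(tested, adj):
                r.adjusted_p[m] = float(a)

    sig = pd.DataFrame(
        {m: [r.adjusted_p.get(m, np.nan) < alpha_level for r in rows]
         for m in methods},
        index=[r.otu_id for r in rows]).astype(int)
    counts = {m: int(sig[m].sum()) for m in methods}
    pattern = sig.apply(
        lambda r: "+".join(m for m in methods if r[m]) or "(none)", axis=1)
    pattern_counts = pattern.value_counts().rename("n_otus")
    return BatchResult(rows=rows, methods=methods, alpha_level=alpha_level,
                       significant_counts=counts, agreement=sig,
                       pattern_counts=pattern_counts)


# ---------------------------------------------------------------------------
# predicted mixture density
# ---------------------------------------------------------------------------

def predicted_density(fit: ModelFit, design: np.ndarray | pd.DataFrame,
                      grid: np.ndarray) -> dict:
    """Model-implied mixture averaged over the design rows.

    Returns the zero point mass mean_i(1 - p_i) and the averaged Beta
    density of the positive part on ``grid``; together they integrate
    to 1 and can be overlaid on an empirical density.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("grid must lie strictly inside (0, 1)")
    X = design.to_numpy(float) if isinstance(design, pd.DataFrame) \
        else np.asarray(design, float)
    theta = fit.estimates()
    ka = fit.alpha_X.shape[1]
    a, second = theta[:ka], theta[ka:-1]
    phi = theta[-1]
    p = _expit(X @ a)
    if fit.model_kind == "CTP":
        mu = _expit(X @ second)
    else:
        mu = _expit(X @ second) / p
        if np.any(mu >= 1):
            raise ValueError("fitted MTP parameters violate mu < 1 on the "
                             "supplied design")
    dens = np.zeros_like(grid)
    for pi, mi in zip(p, mu):
        dens += pi * beta_dist.pdf(grid, mi * phi, (1.0 - mi) * phi)
    dens /= X.shape[0]
    return {"zero_mass": float(np.mean(1.0 - p)), "grid": grid,
            "density": dens}


# ---------------------------------------------------------------------------
# synthetic skin-like fixture
# ---------------------------------------------------------------------------

def synthetic_skin_table(seed: int = 0, n_otus: int = 131,
                         n_samples: int = 261, n_group1: int = 183,
                         effect_fraction: float = 0.3
                         ) -> tuple[AbundanceTable, pd.DataFrame]:
    """Generate a table shaped like a mouse-skin core-OTU study.

    Synthetic stand-in for the real immunization dataset: 131 OTUs x
    261 samples with a binary covariate split 78/183, per-OTU zero
    fractions spread over roughly 0-0.69 with mean near 0.33, and
    right-skewed positive abundances.  A random ``effect_fraction`` of
    OTUs carries a true marginal-mean effect.  Returns the table and a
    metadata frame (columns: group).
    """
    rng = np.random.default_rng(seed)
    x = np.zeros(n_samples)
    x[rng.choice(n_samples, size=n_group1, replace=False)] = 1.0
    X = np.column_stack([np.ones(n_samples), x])
    values = np.empty((n_otus, n_samples))
    has_effect = rng.random(n_otus) < effect_fraction
    from scipy.optimize import brentq
    w1 = n_group1 / n_samples
    for i in range(n_otus):
        # expected overall zero fraction; realized fractions add binomial
        # noise, so cap at 0.58 to keep the observed range under ~0.69
        zf = float(np.clip(rng.beta(2.0, 4.0), 0.005, 0.58))
        alpha1 = float(rng.normal(0.0, 0.3))
        # solve for alpha0 so the population zero fraction (mixing the
        # two groups) equals the target exactly
        alpha0 = float(brentq(
            lambda a0: (1 - w1) * _expit(-a0) + w1 * _expit(-a0 - alpha1)
            - zf, -20.0, 20.0))
        mu0 = float(rng.uniform(0.02, 0.35))      # baseline conditional mean
        nu0 = (1.0 - zf) * mu0
        gamma0 = float(np.log(nu0 / (1.0 - nu0)))
        gamma1 = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)) \
            if has_effect[i] else 0.0
        # keep the support constraint at both covariate levels
        slack = max(gamma0 - alpha0, gamma0 + gamma1 - (alpha0 + alpha1))
        if slack >= -0.05:
            gamma0 -= slack + 0.1
        phi = float(rng.uniform(0.8, 4.0))
        p = _expit(X @ np.array([alpha0, alpha1]))
        mu = _expit(X @ np.array([gamma0, gamma1])) / p
        present = rng.random(n_samples) < p
        y = np.zeros(n_samples)
        idx = np.where(present)[0]
        draws = rng.beta(mu[idx] * phi, (1 - mu[idx]) * phi)
        draws = np.clip(draws, 1e-12, 1 - 1e-12)
        y[idx] = draws
        values[i] = y
    # relative abundances of a "core OTU" subset need not sum to 1,
    # but must not exceed it: rescale samples that do
    colsums = values.sum(axis=0)
    over = colsums > 0.99
    if np.any(over):
        values[:, over] *= 0.99 / colsums[over]
    otu_ids = tuple(f"OTU{i:04d}" for i in range(n_otus))
    sample_ids = tuple(f"S{j:04d}" for j in range(n_samples))
    meta = pd.DataFrame({"group": np.where(x > 0, "imm", "ctrl")},
                        index=pd.Index(sample_ids, name="sample_id"))
    table = AbundanceTable(values, otu_ids, sample_ids)
    return table, meta
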