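"""Pearson correlation of the quality indicators with maturity time.

Reports the full symmetric r matrix with two-tailed p-values (t
transform, n-2 degrees of freedom) and significance flags at 0.05 (*)
and 0.01 (**).  By default the quality table is first reduced to
per-batch means — the indicator trajectories are batch-level phenomena
and a batch is the natural replication unit — but per-fruit correlation
is available via ``by_batch=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import INDICATORS


@dataclass
class CorrelationReport:
    variables: tuple
    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame   # "", "*", "**"
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, r, p, flag, n), upper triangle only."""
        rows = []
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                rows.append({
                    "var1": a, "var2": b,
                    "r": self.r.loc[a, b], "p": self.p.loc[a, b],
                    "flag": self.flags.loc[a, b], "n": int(self.n.loc[a, b]),
                })
        return pd.DataFrame(rows)


def _flag(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_matrix(table: pd.DataFrame, variables=None) -> CorrelationReport:
    """Pairwise-complete Pearson r with two-tailed p per variable pair.

    A perfect correlation (|r| = 1) reports p = 0; a zero-variance
    column makes its pairs undefined (NaN with a warning).
    """
    if variables is None:
        variables = tuple(table.columns)
    variables = tuple(variables)
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(table))
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[variables[i], variables[j]]].dropna()
            x = sub.iloc[:, 0].to_numpy(float)
            y = sub.iloc[:, 1].to_numpy(float)
            n[i, j] = n[j, i] = x.size
            if x.size < 3:
                raise ValueError(
                    f"pair ({variables[i]}, {variables[j]}) has fewer than 3 "
                    "complete cases")
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero variance in pair ({variables[i]}, {variables[j]}); "
                    "correlation undefined", RuntimeWarning, stacklevel=2)
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij = float(np.corrcoef(x, y)[0, 1])
            if abs(rij) >= 1.0 - 1e-15:
                pij = 0.0
            else:
                t = rij * np.sqrt((x.size - 2) / (1.0 - rij**2))
                pij = 2.0 * stats.t.sf(abs(t), x.size - 2)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = list(variables)
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    flags = pdf.map(_flag)
    for v in idx:
        flags.loc[v, v] = ""
    ndf = pd.DataFrame(n, index=idx, columns=idx)
    return CorrelationReport(variables, rdf, pdf, flags, ndf)


def quality_correlation(quality: pd.DataFrame, by_batch: bool = True,
                        variety: str | None = None) -> CorrelationReport:
    """Correlate firmness, pH, SSC, DMC and collection time (day).

    ``by_batch=True`` (default) averages fruit within each batch first;
    ``variety`` restricts to one variety (otherwise pooled).
    """
    q = quality if variety is None else quality[quality["variety"] == variety]
    if q.empty:
        raise ValueError(f"no samples for variety {variety!r}")
    cols = list(INDICATORS) + ["day"]
    if by_batch:
        q = q.groupby(["variety", "batch"], as_index=False)[cols].mean()
    return pearson_matrix(q[cols], cols)
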