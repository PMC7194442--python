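"""Single-chain convergence diagnostics and posterior summaries.

Mirrors a single-run, trace-plot workflow: per-parameter effective sample
size (ESS), a Geweke-style z-score comparing the first 10% of the retained
chain with the last 50% (standard errors adjusted for autocorrelation via
ESS), and the lag-1 autocorrelation.  Parameters with |z| > 3 or ESS < 50
are flagged.  Point estimates are posterior means; intervals are
equal-tailed percentile intervals with linear interpolation, and a
parameter is called significant when its interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

from .mcmc import Chain


def ess_1d(x: np.ndarray) -> float:
    """Effective sample size of one scalar chain."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x[None, :]))


def lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.nan
    return float(x[:-1] @ x[1:] / denom)


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score with ESS-adjusted standard errors."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a, b = x[: int(first * n)], x[int((1 - last) * n):]
    if a.std() == 0 and b.std() == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    se2 = 0.0
    for seg in (a, b):
        var = seg.var(ddof=1)
        ess = ess_1d(seg)
        se2 += var / ess if np.isfinite(ess) and ess > 0 else np.inf
    return float((a.mean() - b.mean()) / np.sqrt(se2))


@dataclass
class DiagnosticsReport:
    table: pd.DataFrame          # per-parameter ess, geweke_z, lag1_acf
    flagged: list[str]           # parameters failing the thresholds

    def ok(self) -> bool:
        return not self.flagged


def diagnostics(chain: Chain, ess_floor: float = 50.0,
                z_limit: float = 3.0) -> DiagnosticsReport:
    """Per-parameter convergence report for a retained chain."""
    if chain.n_retained < 100:
        raise ValueError("diagnostics need at least 100 retained draws")
    rows = []
    flagged = []
    for k, name in enumerate(chain.names):
        x = chain.draws[:, k]
        ess = ess_1d(x)
        z = geweke_z(x)
        rows.append({"parameter": name, "ess": ess, "geweke_z": z,
                     "lag1_acf": lag1_autocorr(x)})
        degenerate = not np.isfinite(ess)
        if degenerate or ess < ess_floor or abs(z) > z_limit:
            flagged.append(name)
    return DiagnosticsReport(table=pd.DataFrame(rows).set_index("parameter"),
                             flagged=flagged)


def summarize_draws(draws: np.ndarray, names: list[str],
                    level: float = 0.95) -> pd.DataFrame:
    """Posterior mean, equal-tailed credible interval and significance."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    tail = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(draws, tail, axis=0)
    hi = np.percentile(draws, 100.0 - tail, axis=0)
    mean = draws.mean(axis=0)
    return pd.DataFrame({
        "mean": mean,
        "lower": lo,
        "upper": hi,
        "significant": (lo > 0) | (hi < 0),
    }, index=pd.Index(names, name="parameter"))


def summarize(chain: Chain, level: float = 0.95) -> pd.DataFrame:
    if chain.n_retained < 1:
        raise ValueError("no retained draws to summarize")
    return summarize_draws(chain.draws, chain.names, level=level)
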