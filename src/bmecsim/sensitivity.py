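"""Global sensitivity analysis: Latin hypercube sampling over parameter
multipliers and partial rank correlation coefficients (PRCC) against the
module outputs and the cell-function score.

PRCC is computed from the precision matrix of the rank-transformed
(parameters + output) correlation matrix — algebraically identical to
residualizing each parameter's ranks and the output ranks on all other
parameters and correlating the residuals, but one matrix inversion per
output instead of thousands of regressions.  Significance uses the
standard t approximation with df = n - 2 - (k - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import ModelNetwork, ParameterSet
from .simulate import SimSettings
from .protocols import StimulusProtocol, make_ogdr_protocol, run_protocol
from .scoring import MODULE_MARKERS, cell_function_score, module_output

log = logging.getLogger(__name__)

OUTPUT_IDS = ["inflammation", "growth", "tight_junction", "cell_function"]


@dataclass
class LHSDesign:
    parameter_ids: list[str]
    multipliers: np.ndarray  # samples x parameters
    seed: int
    low: float = 0.5
    high: float = 2.0

    @property
    def n_samples(self) -> int:
        return self.multipliers.shape[0]

    def row(self, i: int) -> dict[str, float]:
        return dict(zip(self.parameter_ids, self.multipliers[i]))


def lhs_sample(
    parameter_ids: list[str],
    n_samples: int,
    low: float = 0.5,
    high: float = 2.0,
    seed: int = 0,
) -> LHSDesign:
    """Stratified uniform design on [low, high]^k.

    Each column receives exactly one sample per equiprobable stratum, with
    independent stratum permutations per column; reproducible under seed.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if low >= high:
        raise ValueError("low must be < high")
    rng = np.random.default_rng(seed)
    k = len(parameter_ids)
    u = (rng.permuted(np.tile(np.arange(n_samples), (k, 1)), axis=1).T
         + rng.uniform(size=(n_samples, k))) / n_samples
    return LHSDesign(list(parameter_ids), low + (high - low) * u, seed, low, high)


def evaluate_design(
    network: ModelNetwork,
    base_params: ParameterSet,
    design: LHSDesign,
    quiescent_state: np.ndarray,
    protocol: StimulusProtocol | None = None,
    output_ids: list[str] | None = None,
    horizon_stat: str = "endpoint",
    settings: SimSettings | None = None,
    max_failure_fraction: float = 0.05,
) -> np.ndarray:
    """Run the protocol once per design row and summarize the outputs.

    Each row scales the baseline parameters by its multipliers (an intrinsic
    property of the perturbed model, so the whole run including
    pre-equilibration uses the scaled values and scores are normalized to
    each run's own baseline).  Failed simulations yield NaN rows, are
    logged, and may not exceed ``max_failure_fraction``.
    """
    if horizon_stat not in ("endpoint", "auc"):
        raise ValueError("horizon_stat must be 'endpoint' or 'auc'")
    protocol = protocol or make_ogdr_protocol(6.0, 24.0)
    output_ids = list(output_ids or OUTPUT_IDS)
    out = np.full((design.n_samples, len(output_ids)), np.nan)
    failures = []
    for i in range(design.n_samples):
        params = base_params.scaled(design.row(i))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = run_protocol(
                    network, params, quiescent_state, protocol, settings
                )
            for m, oid in enumerate(output_ids):
                if oid == "cell_function":
                    series = cell_function_score(traj).cell_function
                    times = cell_function_score(traj).times
                elif oid in MODULE_MARKERS:
                    times, series = module_output(traj, oid)
                else:
                    raise KeyError(f"unknown output id {oid!r}")
                if horizon_stat == "endpoint":
                    out[i, m] = series[-1]
                else:
                    out[i, m] = np.trapezoid(series, times) / (times[-1] - times[0])
        except Exception as exc:  # noqa: BLE001 - record and continue
            failures.append((i, str(exc)))
    if failures:
        log.warning("%d/%d design rows failed: %s", len(failures),
                    design.n_samples, failures[:3])
    if len(failures) > max_failure_fraction * design.n_samples:
        raise RuntimeError(
            f"{len(failures)}/{design.n_samples} simulations failed; "
            "parameterization too fragile for sensitivity analysis"
        )
    return out


@dataclass
class SensitivityResult:
    parameter_ids: list[str]
    output_ids: list[str]
    prcc: np.ndarray  # parameters x outputs
    p_values: np.ndarray
    n_samples: int
    n_failed: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for m, oid in enumerate(self.output_ids):
            p = self.p_values[:, m]
            order = np.argsort(p)
            p_adj = np.empty_like(p)
            # Benjamini-Hochberg step-up
            ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
            p_adj[order] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
            for j, pid in enumerate(self.parameter_ids):
                recs.append(
                    {
                        "parameter": pid,
                        "output": oid,
                        "prcc": self.prcc[j, m],
                        "p": p[j],
                        "p_adj": p_adj[j],
                        "n": self.n_samples,
                    }
                )
        return pd.DataFrame(recs)


def prcc(design: LHSDesign, outputs: np.ndarray,
         output_ids: list[str] | None = None) -> SensitivityResult:
    """Partial rank correlation of each parameter with each output."""
    X = np.asarray(design.multipliers, dtype=float)
    Y = np.atleast_2d(np.asarray(outputs, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n_out = Y.shape[1]
    output_ids = list(output_ids or OUTPUT_IDS[:n_out])
    k = X.shape[1]

    # collinearity among design columns is a hard error
    rx = np.apply_along_axis(stats.rankdata, 0, X)
    cx = np.corrcoef(rx, rowvar=False)
    bad = np.argwhere(np.triu(np.abs(cx) > 1 - 1e-9, k=1))
    if bad.size:
        pairs = [
            (design.parameter_ids[i], design.parameter_ids[j]) for i, j in bad
        ]
        raise np.linalg.LinAlgError(f"collinear design columns: {pairs}")

    prcc_mat = np.zeros((k, n_out))
    pval_mat = np.ones((k, n_out))
    n_failed = {}
    for m in range(n_out):
        ok = np.isfinite(Y[:, m])
        n_failed[output_ids[m]] = int((~ok).sum())
        n = int(ok.sum())
        if n < 10:
            raise ValueError(
                f"output {output_ids[m]!r}: need >= 10 complete samples, got {n}"
            )
        y = Y[ok, m]
        if np.ptp(y) == 0:
            log.info("output %s constant; PRCC defined as 0", output_ids[m])
            continue  # PRCC 0, p 1 for all parameters
        Z = np.column_stack([np.apply_along_axis(stats.rankdata, 0, X[ok]),
                             stats.rankdata(y)])
        C = np.corrcoef(Z, rowvar=False)
        if np.linalg.cond(C) < 1e10:
            P = np.linalg.inv(C)
            r = -P[:k, k] / np.sqrt(P.diagonal()[:k] * P[k, k])
        else:
            # degenerate (e.g. output identical to an input): fall back to
            # explicit rank-residualization, which handles the rank-deficient
            # case gracefully
            r = np.empty(k)
            for j in range(k):
                others = np.column_stack(
                    [np.ones(n), np.delete(Z[:, :k], j, axis=1)]
                )
                bx = np.linalg.lstsq(others, Z[:, j], rcond=None)[0]
                by = np.linalg.lstsq(others, Z[:, k], rcond=None)[0]
                ex, ey = Z[:, j] - others @ bx, Z[:, k] - others @ by
                denom = np.sqrt((ex @ ex) * (ey @ ey))
                r[j] = (ex @ ey) / denom if denom > 0 else 0.0
        r = np.clip(r, -1.0, 1.0)
        df = n - 2 - (k - 1)
        if df <= 0:
            raise ValueError(
                f"not enough samples (n={n}) for {k} parameters (df={df})"
            )
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r**2))
        prcc_mat[:, m] = r
        pval_mat[:, m] = 2 * stats.t.sf(np.abs(t), df)
    return SensitivityResult(
        list(design.parameter_ids), output_ids, prcc_mat, pval_mat,
        X.shape[0], n_failed,
    )


def rank_targets(
    result: SensitivityResult,
    output_id: str,
    top_k: int = 10,
    alpha: float = 0.05,
) -> list[tuple[str, float, float]]:
    """Parameters ranked by |PRCC| (descending) for one output.

    Only entries with p < alpha are eligible; ties in |PRCC| break
    lexicographically by parameter id.
    """
    try:
        m = result.output_ids.index(output_id)
    except ValueError:
        raise KeyError(f"unknown output id {output_id!r}") from None
    rows = [
        (pid, float(result.prcc[j, m]), float(result.p_values[j, m]))
        for j, pid in enumerate(result.parameter_ids)
        if result.p_values[j, m] < alpha
    ]
    rows.sort(key=lambda r: (-abs(r[1]), r[0]))
    return rows[:top_k]
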