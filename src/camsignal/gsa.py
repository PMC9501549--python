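"""Global sensitivity analysis: LHS sampling, monotonicity screening,
partial rank correlation coefficients, and KS regionalized sensitivity.

The pipeline mirrors the standard LHS–PRCC recipe: every parameter is
perturbed over ±90% of its baseline, one-at-a-time monotonicity screening
truncates each range to its largest monotone subrange (PRCC assumes
monotone input–output relations), a Latin hypercube is drawn over the
retained ranges, the model is evaluated once per sample, and the PRCC of
each parameter is the partial correlation of its ranks with the output
ranks controlling for all other parameters' ranks.  Significance uses the
t-statistic with n − 2 − k degrees of freedom (k = number of controlled
parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import integrate, observables
from .parameters import ParameterSet
from .stimulus import make_protocol

__all__ = ["GSAConfig", "PRCCTable", "lhs_sample", "monotonicity_screen",
           "prcc", "ks_regionalized", "run_gsa", "make_evaluator",
           "DEFAULT_GSA_PARAMETERS", "CONCENTRATION_PARAMETERS"]

#: parameters varied in the reference CaM₄ sensitivity campaign: the nine-state
#: CaM rates, target binding/catalysis rates and every protein concentration
#: that feeds back on CaM₄ stability, plus the reduced-PKA ceiling.
DEFAULT_GSA_PARAMETERS = (
    "kon_NT", "kon_NR", "koff_NT", "koff_NR",
    "kon_CT", "kon_CR", "koff_CT", "koff_CR",
    "K1", "kcat3", "kcat5", "kcat11", "kcat14", "kcat15", "kcat16",
    "Km5", "Km9", "Km11", "Km15", "Km16",
    "kc1b", "kc3f", "kc3b", "kc5f", "kc5b1",
    "pka_max",
    "AC1_T", "CaMKII_T", "PDE4D_T", "PDE1_T", "PP2B_T", "PP2A_T",
    "PP1_T", "I1_T",
)

CONCENTRATION_PARAMETERS = (
    "AC1_T", "CaMKII_T", "PDE4D_T", "PDE1_T", "PP2B_T", "PP2A_T",
    "PP1_T", "I1_T",
)


@dataclass(frozen=True)
class GSAConfig:
    parameters: tuple[str, ...] = DEFAULT_GSA_PARAMETERS
    span: float = 0.9                 # ±fraction of baseline
    n_samples: int = 5000
    observable: str = "CaM4_total"
    protocol: str = "LFS"
    summary: str = "time_average"
    mode: str = "reduced_pka"
    seed: int = 0
    prcc_alpha: float = 1e-4
    ks_alpha: float = 0.01
    screen_points: int = 21
    screen_spearman: float = 0.8
    rtol: float = 1e-6
    atol: float = 1e-9
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def resolved_ranges(self, p: ParameterSet) -> dict[str, tuple[float, float]]:
        """Per-parameter (low, high); default baseline × [1−span, 1+span]."""
        out = {}
        for name in self.parameters:
            if name in self.ranges:
                lo, hi = self.ranges[name]
            else:
                base = getattr(p, name)
                lo, hi = base * (1.0 - self.span), base * (1.0 + self.span)
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
            out[name] = (float(lo), float(hi))
        if self.n_samples < 10 * len(self.parameters):
            warnings.warn(
                f"n_samples={self.n_samples} < 10 × {len(self.parameters)} "
                "parameters; PRCC estimates may be noisy", stacklevel=2)
        return out


def lhs_sample(ranges: dict[str, tuple[float, float]], n_samples: int,
               seed: int) -> pd.DataFrame:
    """Latin hypercube: one uniform draw per stratum per parameter, with
    independent random stratum permutations pairing the columns."""
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in ranges.items():
        strata = (np.arange(n_samples) + rng.uniform(size=n_samples)) / n_samples
        cols[name] = lo + (hi - lo) * rng.permutation(strata)
    return pd.DataFrame(cols)


def monotonicity_screen(values: np.ndarray, responses: np.ndarray,
                        spearman_threshold: float = 0.8
                        ) -> tuple[float, float] | None:
    """Largest contiguous subrange where the response is monotone.

    Returns the (low, high) subrange, or None when the response carries no
    rank correlation anywhere (flat, or below the Spearman threshold) and
    the parameter should be excluded.  Of a unimodal response the longer
    monotone limb is kept; ties break to the lower side.
    """
    values = np.asarray(values, float)
    responses = np.asarray(responses, float)
    ok = np.isfinite(responses)
    if ok.sum() < 3:
        return None
    values, responses = values[ok], responses[ok]
    scale = np.max(np.abs(responses))
    if scale <= 0 or np.ptp(responses) < 1e-9 * scale:
        return None                    # flat: no correlation
    tol = 1e-9 * scale

    # maximal monotone runs (either direction)
    best: tuple[int, int] | None = None
    i = 0
    n = len(values)
    while i < n - 1:
        j = i + 1
        direction = 0
        while j < n:
            step = responses[j] - responses[j - 1]
            d = 0 if abs(step) <= tol else (1 if step > 0 else -1)
            if direction == 0:
                direction = d
            elif d != 0 and d != direction:
                break
            j += 1
        if best is None or (j - 1 - i) > (best[1] - best[0]):
            best = (i, j - 1)
        i = j - 1
    lo, hi = best
    if hi - lo + 1 < 3:
        return None
    rho = stats.spearmanr(values[lo:hi + 1], responses[lo:hi + 1]).statistic
    if not np.isfinite(rho) or abs(rho) < spearman_threshold:
        return None
    return float(values[lo]), float(values[hi])


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


@dataclass(frozen=True)
class PRCCTable:
    """Per-parameter PRCC with p-values and the ranges actually sampled."""

    table: pd.DataFrame               # index=parameter; prcc, p_value, significant, low, high
    observable: str
    protocol: str
    summary: str
    n_samples: int
    seed: int
    alpha: float

    def __getitem__(self, parameter: str) -> float:
        return float(self.table.loc[parameter, "prcc"])

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def prcc(samples: pd.DataFrame, responses: np.ndarray, alpha: float = 1e-4,
         **meta) -> PRCCTable:
    """Partial rank correlation of each sample column with the response.

    Ranks are residualized against all other columns (with intercept) by
    least squares; the coefficient is the Pearson correlation of the two
    residual vectors.
    """
    y = np.asarray(responses, float)
    n, k = samples.shape
    if n <= k + 2:
        raise ValueError("need n_samples > n_parameters + 2")
    for name in samples.columns:
        if np.ptp(samples[name].to_numpy()) == 0:
            raise ValueError(f"constant (rank-degenerate) column: {name}")
    rx = _rank(samples.to_numpy())
    ry = _rank(y)
    rows = {}
    dof = n - 2 - (k - 1)
    for j, name in enumerate(samples.columns):
        others = np.column_stack([np.ones(n), np.delete(rx, j, axis=1)])
        beta_x, *_ = np.linalg.lstsq(others, rx[:, j], rcond=None)
        beta_y, *_ = np.linalg.lstsq(others, ry, rcond=None)
        ex = rx[:, j] - others @ beta_x
        ey = ry - others @ beta_y
        denom = np.sqrt((ex @ ex) * (ey @ ey))
        r = float(ex @ ey / denom) if denom > 0 else 0.0
        r = min(1.0, max(-1.0, r))
        if abs(r) >= 1.0:
            pval = 0.0
        else:
            tstat = r * np.sqrt(dof / (1.0 - r * r))
            pval = float(2.0 * stats.t.sf(abs(tstat), dof))
        rows[name] = {"prcc": r, "p_value": pval, "significant": pval < alpha}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.astype({"prcc": float, "p_value": float, "significant": bool})
    meta.setdefault("observable", "")
    meta.setdefault("protocol", "")
    meta.setdefault("summary", "")
    meta.setdefault("n_samples", n)
    meta.setdefault("seed", -1)
    return PRCCTable(table=table, alpha=alpha, **meta)


def ks_regionalized(samples: pd.DataFrame, accepted: np.ndarray,
                    alpha: float = 0.01) -> pd.DataFrame:
    """Two-sample KS contrast of accepted vs rejected marginal distributions.

    A parameter is flagged sensitive when the accepted and rejected
    cumulative frequency distributions of its sampled values differ at
    ``p < alpha``.
    """
    accepted = np.asarray(accepted, bool)
    if accepted.all() or (~accepted).all():
        raise ValueError("acceptance labels give no contrast "
                         "(all accepted or all rejected)")
    rows = {}
    for name in samples.columns:
        x = samples[name].to_numpy()
        res = stats.ks_2samp(x[accepted], x[~accepted])
        rows[name] = {"ks_statistic": float(res.statistic),
                      "p_value": float(res.pvalue),
                      "sensitive": res.pvalue < alpha}
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.astype({"ks_statistic": float, "p_value": float,
                       "sensitive": bool})


def make_evaluator(p: ParameterSet, cfg: GSAConfig):
    """Model callable: {parameter: value} → scalar observable summary."""
    proto = make_protocol(cfg.protocol, Ca_basal=p.Ca_basal, tau=p.tau_decay)

    def evaluate(assignment: dict[str, float]) -> float:
        pv = p.replace(**assignment)
        r = integrate(pv, proto, mode=cfg.mode, rtol=cfg.rtol, atol=cfg.atol,
                      output_dt=0.01)
        return observables(r, cfg.observable, cfg.summary)

    return evaluate


def run_gsa(cfg: GSAConfig, p: ParameterSet, screen: bool = True,
            checkpoint: str | None = None, progress: bool = False) -> PRCCTable:
    """Full pipeline: screen → LHS → model evaluations → PRCC.

    ``checkpoint`` names an .npz file holding completed evaluations;
    interrupted runs resume from it (the sample matrix is reproducible
    from the seed, so only responses are stored).
    """
    evaluate = make_evaluator(p, cfg)
    ranges = cfg.resolved_ranges(p)

    if screen:
        kept = {}
        for name, (lo, hi) in ranges.items():
            grid = np.linspace(lo, hi, cfg.screen_points)
            resp = np.empty_like(grid)
            for i, v in enumerate(grid):
                try:
                    resp[i] = evaluate({name: float(v)})
                except Exception as exc:
                    warnings.warn(f"screen failure at {name}={v:.4g}: {exc}",
                                  stacklevel=2)
                    resp[i] = np.nan
            sub = monotonicity_screen(grid, resp, cfg.screen_spearman)
            if sub is not None:
                kept[name] = sub
        if not kept:
            raise RuntimeError("monotonicity screen excluded every parameter")
        ranges = kept

    samples = lhs_sample(ranges, cfg.n_samples, cfg.seed)
    responses = np.full(cfg.n_samples, np.nan)
    start = 0
    if checkpoint is not None:
        try:
            done = np.load(checkpoint)["responses"]
            responses[:len(done)] = done
            start = len(done)
        except (FileNotFoundError, KeyError):
            pass
    failures = 0
    for i in range(start, cfg.n_samples):
        row = samples.iloc[i].to_dict()
        try:
            responses[i] = evaluate(row)
        except Exception:
            failures += 1
            if failures > max(1, 0.01 * cfg.n_samples):
                raise RuntimeError(
                    f"more than 1% of model evaluations failed "
                    f"({failures}/{i + 1}); aborting") from None
        if checkpoint is not None and (i + 1) % 50 == 0:
            np.savez(checkpoint, responses=responses[:i + 1])
        if progress and (i + 1) % 50 == 0:
            print(f"  gsa: {i + 1}/{cfg.n_samples} evaluations")
    keep = np.isfinite(responses)
    table = prcc(samples[keep], responses[keep], alpha=cfg.prcc_alpha,
                 observable=cfg.observable, protocol=cfg.protocol,
                 summary=cfg.summary, n_samples=int(keep.sum()), seed=cfg.seed)
    lohi = pd.DataFrame(ranges, index=["low", "high"]).T
    table.table["low"] = lohi["low"]
    table.table["high"] = lohi["high"]
    return table
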