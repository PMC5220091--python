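"""PDM filter-bank outputs, cross-term screening, and associated nonlinear
functions (ANFs).

Each global PDM g_i acts as a linear filter on its input; the filter output
u_i(n) is passed through a subject-specific cubic polynomial
f_i(u) = a1 u + a2 u^2 + a3 u^3.  Significant intermodulation between the
two inputs is captured by pair products u_{i,BP} * u_{j,CO2}, screened at
the 99% level with the Fisher-z (w-statistic) test on their correlation
with the output.  All polynomials, retained cross-terms and a global
intercept are fitted in one joint least-squares regression.

The slope of the best linear fit to f_i over the subject's own operating
range of u_i is the ANF gain — the candidate biomarker of sympathetic
cerebrovascular control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .laguerre import PredictionResult, _nmse
from .pdm import GlobalPDMSet
from .series import SubjectRecording, UniformSeries

__all__ = [
    "PDMOutputs",
    "CrossTerm",
    "CrossTermSet",
    "pdm_filter_outputs",
    "screen_cross_terms",
    "anf_gain",
    "PDMANFModel",
    "PDMANFResults",
    "fit_anfs",
    "predict_pdm_model",
]

logger = logging.getLogger(__name__)


@dataclass
class PDMOutputs:
    """Filter-bank outputs u_{i,BP}(n), u_{i,CO2}(n) for one recording."""

    u_bp: np.ndarray       # (T, H)
    u_co2: np.ndarray      # (T, H)
    burn_in: int           # first M-1 samples excluded from fitting
    fs: float = 1.0

    @property
    def H(self) -> int:
        return self.u_bp.shape[1]

    @property
    def T(self) -> int:
        return self.u_bp.shape[0]


@dataclass
class CrossTerm:
    i: int                 # BP-PDM index (0-based)
    j: int                 # CO2-PDM index (0-based)
    r: float
    w: float
    retained: bool
    coefficient: float | None = None


@dataclass
class CrossTermSet:
    terms: list[CrossTerm] = field(default_factory=list)
    level: float = 0.99
    threshold: float = float("nan")   # critical |w| * sqrt(n-3)

    @property
    def retained(self) -> list[CrossTerm]:
        return [t for t in self.terms if t.retained]

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return [(t.i, t.j) for t in self.retained]


def pdm_filter_outputs(pdms_bp: GlobalPDMSet, pdms_co2: GlobalPDMSet,
                       rec: SubjectRecording,
                       demean_inputs: bool = True) -> PDMOutputs:
    """Causal convolution of each input with each of its global PDMs.

    Inputs are treated as zero before their first sample (same convention
    as kernel estimation); the first M-1 samples are flagged as burn-in.
    """
    if pdms_bp.M != pdms_co2.M:
        raise ValueError("PDM sets disagree on memory M")
    M = pdms_bp.M
    T = rec.n_samples
    if T <= M:
        raise ValueError(f"recording length {T} too short for memory {M}")
    p = rec.bp.values
    c = rec.co2.values
    if demean_inputs:
        p = p - p.mean()
        c = c - c.mean()
    u_bp = np.column_stack(
        [np.convolve(p, pdms_bp.pdms[:, i])[:T] for i in range(pdms_bp.H)])
    u_co2 = np.column_stack(
        [np.convolve(c, pdms_co2.pdms[:, i])[:T] for i in range(pdms_co2.H)])
    return PDMOutputs(u_bp=u_bp, u_co2=u_co2, burn_in=M - 1, fs=rec.fs)


def screen_cross_terms(u: PDMOutputs, flow: UniformSeries,
                       level: float = 0.99) -> CrossTermSet:
    """w-statistic screening of BP x CO2 PDM-output pair products.

    For each pair (i, j) the Pearson correlation r between
    u_{i,BP} * u_{j,CO2} and the output is Fisher-transformed,
    w = atanh(r), and the pair is retained iff
    ``|w| * sqrt(n - 3) > z``, the two-sided standard-normal quantile at
    ``level`` (z = 2.576 at 99%).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    y = flow.values[u.burn_in:]
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 post-burn-in samples")
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = CrossTermSet(level=level, threshold=float(z))
    yc = y - y.mean()
    ynorm = np.sqrt(np.sum(yc ** 2))
    for i in range(u.H):
        for j in range(u.H):
            prod = u.u_bp[u.burn_in:, i] * u.u_co2[u.burn_in:, j]
            pc = prod - prod.mean()
            pnorm = np.sqrt(np.sum(pc ** 2))
            if pnorm == 0.0 or ynorm == 0.0:
                logger.info("cross-term (%d, %d): constant series, skipped",
                            i, j)
                continue
            r = float(np.dot(pc, yc) / (pnorm * ynorm))
            r = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
            w = float(np.arctanh(r))
            retained = abs(w) * np.sqrt(n - 3) > z
            out.terms.append(CrossTerm(i=i, j=j, r=r, w=w,
                                       retained=bool(retained)))
    return out


def anf_gain(coeffs, u_samples) -> float:
    """Slope of the best linear fit to the ANF over observed u samples.

    The polynomial f(u) = a1 u + a2 u^2 + ... is evaluated at the subject's
    own post-burn-in filter outputs and regressed on u by ordinary least
    squares, so the gain is weighted by the subject's operating range.
    """
    a = np.asarray(coeffs, float)
    u = np.asarray(u_samples, float)
    if np.unique(u).size < 2:
        raise ValueError("need at least 2 distinct u values")
    f = sum(a[k] * u ** (k + 1) for k in range(a.size))
    uc = u - u.mean()
    return float(np.dot(uc, f) / np.dot(uc, uc))


class PDMANFModel:
    """Joint polynomial regression of flow on PDM filter-bank outputs.

    Parameters
    ----------
    flow : UniformSeries
        Observed output series (full length; burn-in handled internally).
    outputs : PDMOutputs
        Filter-bank outputs from :func:`pdm_filter_outputs`.
    cross : CrossTermSet, optional
        Screened cross-terms; screened at ``screen_level`` when omitted.
    order : int
        Polynomial order of the ANFs (cubic by default).
    """

    def __init__(self, flow: UniformSeries, outputs: PDMOutputs,
                 cross: CrossTermSet | None = None, order: int = 3,
                 screen_level: float = 0.99):
        if order < 1:
            raise ValueError("order must be >= 1")
        self.flow = flow
        self.outputs = outputs
        self.order = order
        if cross is None:
            cross = screen_cross_terms(outputs, flow, level=screen_level)
        self.cross = cross
        self.k_params = 1 + 2 * outputs.H * order + len(cross.pairs)

    def _design(self):
        u = self.outputs
        s = slice(u.burn_in, None)
        cols = [np.ones(u.T - u.burn_in)]
        for block in (u.u_bp, u.u_co2):
            for i in range(u.H):
                for k in range(1, self.order + 1):
                    cols.append(block[s, i] ** k)
        for (i, j) in self.cross.pairs:
            cols.append(u.u_bp[s, i] * u.u_co2[s, j])
        V = np.column_stack(cols)
        y = self.flow.values[s]
        return V, y

    def fit(self) -> "PDMANFResults":
        V, y = self._design()
        S, K = V.shape
        if S <= K:
            raise ValueError(
                f"unidentifiable ANF model: {S} samples for {K} parameters")
        beta, _, rank, _ = np.linalg.lstsq(V, y, rcond=None)
        if rank < K:
            raise np.linalg.LinAlgError(
                "rank-deficient ANF design: collinear PDM outputs")
        return PDMANFResults(self, beta, V, y)


class PDMANFResults:
    """Fitted ANFs: polynomial coefficients, cross-terms, gains, NMSE."""

    def __init__(self, model: PDMANFModel, beta: np.ndarray,
                 V: np.ndarray, y: np.ndarray):
        self.model = model
        self.params = beta
        H, order = model.outputs.H, model.order
        self.intercept = float(beta[0])
        blk = H * order
        self.coeffs_bp = beta[1:1 + blk].reshape(H, order)
        self.coeffs_co2 = beta[1 + blk:1 + 2 * blk].reshape(H, order)
        for t, c in zip(model.cross.retained, beta[1 + 2 * blk:]):
            t.coefficient = float(c)
        self.fittedvalues = V @ beta
        self.resid = y - self.fittedvalues
        self.nmse = _nmse(y, self.fittedvalues)
        u = model.outputs
        s = slice(u.burn_in, None)
        self.gains_bp = np.array(
            [anf_gain(self.coeffs_bp[i], u.u_bp[s, i]) for i in range(H)])
        self.gains_co2 = np.array(
            [anf_gain(self.coeffs_co2[i], u.u_co2[s, i]) for i in range(H)])

    @property
    def cross(self) -> CrossTermSet:
        return self.model.cross

    @property
    def rss(self) -> float:
        return float(np.sum(self.resid ** 2))

    def predict(self, outputs: PDMOutputs | None = None,
                observed: UniformSeries | None = None) -> PredictionResult:
        """Evaluate the fitted PDM/ANF model on (possibly new) filter outputs."""
        u = self.model.outputs if outputs is None else outputs
        s = slice(u.burn_in, None)
        H, order = u.H, self.model.order
        yhat = np.full(u.T - u.burn_in, self.intercept)
        for i in range(H):
            for k in range(1, order + 1):
                yhat += self.coeffs_bp[i, k - 1] * u.u_bp[s, i] ** k
                yhat += self.coeffs_co2[i, k - 1] * u.u_co2[s, i] ** k
        for t in self.model.cross.retained:
            yhat += t.coefficient * u.u_bp[s, t.i] * u.u_co2[s, t.j]
        pred = UniformSeries(yhat, fs=u.fs, label="flow_pred", units="cm/s")
        if observed is None:
            return PredictionResult(predicted=pred, residual=None, nmse=None)
        obs = observed.values[u.burn_in:]
        resid = obs - yhat
        return PredictionResult(
            predicted=pred,
            residual=UniformSeries(resid, fs=u.fs, label="residual",
                                   units="cm/s"),
            nmse=_nmse(obs, yhat))

    def summary(self) -> str:
        lines = [
            "PDM / ANF model",
            "=" * 52,
            f"PDMs per input (H):    {self.model.outputs.H}",
            f"ANF order:             {self.model.order}",
            f"retained cross-terms:  {len(self.model.cross.pairs)}",
            f"training NMSE:         {self.nmse:.4f}",
            "",
            "ANF gains (slope of best linear fit over observed u):",
            "  BP : " + np.array2string(self.gains_bp, precision=4),
            "  CO2: " + np.array2string(self.gains_co2, precision=4),
        ]
        return "\n".join(lines)


def fit_anfs(outputs: PDMOutputs, cross: CrossTermSet | None,
             flow: UniformSeries, order: int = 3) -> PDMANFResults:
    """Functional wrapper: joint ANF regression on filter-bank outputs."""
    return PDMANFModel(flow, outputs, cross=cross, order=order).fit()


def predict_pdm_model(results: PDMANFResults, outputs: PDMOutputs,
                      observed: UniformSeries | None = None) -> PredictionResult:
    """Functional wrapper around :meth:`PDMANFResults.predict`."""
    return results.predict(outputs, observed=observed)
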