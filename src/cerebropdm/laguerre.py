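"""Discrete Laguerre expansion of dual-input second-order Volterra models.

The model relates spontaneous arterial blood pressure P(n) and end-tidal CO2
C(n) fluctuations to cerebral blood flow velocity F(n)::

    F(n) = k0 + sum_m kP(m) P(n-m) + sum_m kC(m) C(n-m)
         + sum_{m1,m2} kPP(m1,m2) P(n-m1) P(n-m2)
         + sum_{m1,m2} kCC(m1,m2) C(n-m1) C(n-m2)
         + sum_{m1,m2} kPC(m1,m2) P(n-m1) C(n-m2) + e(n)

Kernels are expanded on L discrete orthonormal Laguerre functions
b_j(m), j = 0..L-1, whose exponential decay rate is governed by a single
parameter alpha in (0, 1).  The expansion turns kernel estimation into an
ordinary least-squares regression on the Laguerre-filtered inputs and their
pairwise products.  At the cohort's working point (alpha = 0.5, L = 5) the
regression has 66 free parameters.

The self-kernels kPP, kCC are symmetric, so only the L(L+1)/2 unique
coefficient pairs (j1, j2), j2 <= j1, are estimated; the cross-kernel kPC has
no symmetry and carries the full L x L asymmetric coefficient set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .series import SubjectRecording, UniformSeries

__all__ = [
    "LaguerreBasis",
    "KernelCoefficients",
    "VolterraKernels",
    "PredictionResult",
    "choose_memory",
    "discrete_laguerre_basis",
    "convolve_basis",
    "count_free_parameters",
    "build_regressor_matrix",
    "triangular_pairs",
    "cross_pairs",
    "estimate_kernels",
    "predict_output",
    "LaguerreVolterraModel",
    "LaguerreVolterraResults",
]

#: default decay threshold for the memory rule; chosen so the truncated
#: basis is orthonormal to better than 1e-8 (a looser 1e-4 leaves ~1.4e-8
#: of tail mass in the Gram matrix at alpha = 0.5, L = 5)
DEFAULT_MEMORY_EPSILON = 2e-5


class IdentifiabilityWarning(UserWarning):
    """Fewer than ~5 samples per free parameter (overfitting risk)."""


def _laguerre_value(alpha: float, j: int, m: int) -> float:
    # direct evaluation; binom(m, k) = 0 for k > m is handled by math.comb
    s = 0.0
    for k in range(j + 1):
        s += ((-1) ** k) * math.comb(m, k) * math.comb(j, k) \
            * alpha ** (j - k) * (1.0 - alpha) ** k
    return alpha ** ((m - j) / 2.0) * math.sqrt(1.0 - alpha) * s


@dataclass(frozen=True)
class LaguerreBasis:
    """Discrete orthonormal Laguerre functions b_j(m), j = 0..L-1, m = 0..M-1.

    ``B[m, j] = b_j(m)``.  Columns are orthonormal to numerical precision
    when M is chosen by the decay rule :func:`choose_memory`.
    """

    alpha: float
    L: int
    M: int
    B: np.ndarray

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 1 <= self.L <= self.M:
            raise ValueError("need 1 <= L <= M")
        if self.B.shape != (self.M, self.L) or not np.all(np.isfinite(self.B)):
            raise ValueError("basis matrix malformed")


def choose_memory(alpha: float, L: int,
                  epsilon: float = DEFAULT_MEMORY_EPSILON) -> int:
    """Smallest memory M such that |b_j(m)| < epsilon for all j < L, m >= M.

    Returns at least L + 1.  Raises if the search does not converge within
    a hard cap of ~10 L / (1 - alpha) lags (invalid parameters), or if
    epsilon is not in (0, 1): the exponential decay never reaches zero.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    # envelope decays like alpha^(m/2): size the search horizon from the
    # decay rate and threshold, with a polynomial-growth margin in L
    decay_lags = int(math.ceil(4.0 * math.log(1.0 / epsilon)
                               / max(math.log(1.0 / alpha), 1e-12)))
    cap = max(int(math.ceil(10.0 * L / (1.0 - alpha))),
              decay_lags + 10 * L, L + 2)
    last_above = -1
    for m in range(cap):
        if any(abs(_laguerre_value(alpha, j, m)) >= epsilon for j in range(L)):
            last_above = m
    if last_above == cap - 1:
        raise ValueError(
            f"decay rule did not converge within {cap} lags "
            f"(alpha={alpha}, L={L}, epsilon={epsilon})")
    return max(last_above + 1, L + 1)


def discrete_laguerre_basis(alpha: float, L: int,
                            M: int | None = None) -> LaguerreBasis:
    """Build the M x L discrete Laguerre basis matrix.

    When ``M`` is omitted it is fixed by the decay rule
    :func:`choose_memory`.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if M is None:
        M = choose_memory(alpha, L)
    if L > M:
        raise ValueError("need L <= M")
    B = np.empty((M, L))
    for j in range(L):
        for m in range(M):
            B[m, j] = _laguerre_value(alpha, j, m)
    return LaguerreBasis(alpha=alpha, L=L, M=M, B=B)


def convolve_basis(basis: LaguerreBasis, x) -> np.ndarray:
    """Causal convolution of x with every basis function (zero prehistory).

    Column j holds (b_j * x)(n) = sum_{m=0}^{M-1} b_j(m) x(n-m), with x
    treated as zero before its first sample.  Output has the length of x.
    """
    xv = x.values if isinstance(x, UniformSeries) else np.asarray(x, float)
    T = xv.size
    if T < basis.M:
        raise ValueError(f"series length {T} shorter than memory {basis.M}")
    out = np.empty((T, basis.L))
    for j in range(basis.L):
        out[:, j] = np.convolve(xv, basis.B[:, j])[:T]
    return out


def count_free_parameters(L: int) -> int:
    """Free parameters of the dual-input second-order model.

    1 constant + 2L first-order + 2 * L(L+1)/2 triangular self-kernel sets
    + L^2 full asymmetric cross-kernel set.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return 1 + 2 * L + L * (L + 1) + L * L


def triangular_pairs(L: int) -> list[tuple[int, int]]:
    """Self-kernel coefficient ordering: (j1, j2), j2 <= j1, lexicographic."""
    return [(j1, j2) for j1 in range(L) for j2 in range(j1 + 1)]


def cross_pairs(L: int) -> list[tuple[int, int]]:
    """Cross-kernel coefficient ordering: all (j1, j2), lexicographic."""
    return [(j1, j2) for j1 in range(L) for j2 in range(L)]


def build_regressor_matrix(vP: np.ndarray, vC: np.ndarray, M: int) -> np.ndarray:
    """Assemble the OLS regressor matrix V = [1 | VP | VC | VPP | VCC | VPC].

    Rows are restricted to n >= M-1 (convolution burn-in removed), so the
    output has S = T - (M-1) rows and ``count_free_parameters(L)`` columns.
    """
    vP = np.asarray(vP, float)
    vC = np.asarray(vC, float)
    if vP.shape != vC.shape or vP.ndim != 2:
        raise ValueError("vP and vC must share shape (T, L)")
    T, L = vP.shape
    if T < M:
        raise ValueError("series shorter than memory")
    tri = triangular_pairs(L)
    crs = cross_pairs(L)
    cols = [np.ones((T, 1)), vP, vC]
    cols.append(np.column_stack([vP[:, a] * vP[:, b] for a, b in tri]))
    cols.append(np.column_stack([vC[:, a] * vC[:, b] for a, b in tri]))
    cols.append(np.column_stack([vP[:, a] * vC[:, b] for a, b in crs]))
    V = np.concatenate(cols, axis=1)
    return V[M - 1:, :]


@dataclass
class KernelCoefficients:
    """Laguerre expansion coefficients beta of the dual-input model."""

    k0: float
    beta_p: np.ndarray      # (L,)
    beta_c: np.ndarray      # (L,)
    beta_pp: np.ndarray     # (L(L+1)/2,) triangular, (j1, j2) lexicographic
    beta_cc: np.ndarray     # (L(L+1)/2,)
    beta_pc: np.ndarray     # (L*L,) full asymmetric, (j1, j2) lexicographic

    @property
    def L(self) -> int:
        return self.beta_p.size

    @classmethod
    def from_flat(cls, beta: np.ndarray, L: int) -> "KernelCoefficients":
        beta = np.asarray(beta, float)
        if beta.size != count_free_parameters(L):
            raise ValueError("coefficient vector length inconsistent with L")
        ntri = L * (L + 1) // 2
        idx = np.cumsum([1, L, L, ntri, ntri, L * L])
        parts = np.split(beta, idx[:-1])
        return cls(k0=float(parts[0][0]), beta_p=parts[1], beta_c=parts[2],
                   beta_pp=parts[3], beta_cc=parts[4], beta_pc=parts[5])

    def to_flat(self) -> np.ndarray:
        return np.concatenate([[self.k0], self.beta_p, self.beta_c,
                               self.beta_pp, self.beta_cc, self.beta_pc])


@dataclass
class VolterraKernels:
    """Time-domain kernels reconstructed from Laguerre coefficients."""

    kP: np.ndarray          # (M,)
    kC: np.ndarray          # (M,)
    kPP: np.ndarray         # (M, M), exactly symmetric
    kCC: np.ndarray         # (M, M), exactly symmetric
    kPC: np.ndarray         # (M, M)
    basis: LaguerreBasis

    def __post_init__(self):
        if not (np.array_equal(self.kPP, self.kPP.T)
                and np.array_equal(self.kCC, self.kCC.T)):
            raise ValueError("self-kernels must be exactly symmetric")

    @property
    def M(self) -> int:
        return self.kP.size


def _self_coeff_matrix(beta_tri: np.ndarray, L: int) -> np.ndarray:
    """Symmetric coefficient matrix sharing each off-diagonal triangular
    coefficient between (j1, j2) and (j2, j1)."""
    C = np.zeros((L, L))
    for val, (a, b) in zip(beta_tri, triangular_pairs(L)):
        if a == b:
            C[a, a] = val
        else:
            C[a, b] = C[b, a] = val / 2.0
    return C


def reconstruct_kernels(coeffs: KernelCoefficients,
                        basis: LaguerreBasis) -> VolterraKernels:
    """Map expansion coefficients to time-domain kernels."""
    B = basis.B
    L = basis.L
    kP = B @ coeffs.beta_p
    kC = B @ coeffs.beta_c
    Cpp = _self_coeff_matrix(coeffs.beta_pp, L)
    Ccc = _self_coeff_matrix(coeffs.beta_cc, L)
    kPP = B @ Cpp @ B.T
    kPP = (kPP + kPP.T) / 2.0
    kCC = B @ Ccc @ B.T
    kCC = (kCC + kCC.T) / 2.0
    kPC = B @ coeffs.beta_pc.reshape(L, L) @ B.T
    return VolterraKernels(kP=kP, kC=kC, kPP=kPP, kCC=kCC, kPC=kPC,
                           basis=basis)


@dataclass
class PredictionResult:
    """Model output, residual and normalized mean squared error.

    NMSE is the residual power over the power of the mean-removed observed
    output, evaluated after burn-in removal; it is None when no observed
    output was supplied.
    """

    predicted: UniformSeries
    residual: UniformSeries | None
    nmse: float | None


def _nmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    resid = observed - predicted
    denom = float(np.sum((observed - observed.mean()) ** 2))
    if denom == 0.0:
        return float("inf") if np.any(resid) else 0.0
    return float(np.sum(resid ** 2) / denom)


def _lag_matrix(x: np.ndarray, M: int) -> np.ndarray:
    """X[n, m] = x(n - m) with zero prehistory; shape (T, M)."""
    T = x.size
    X = np.zeros((T, M))
    for m in range(M):
        X[m:, m] = x[:T - m]
    return X


def predict_output(kernels: VolterraKernels, bp, co2, k0: float = 0.0,
                   observed=None) -> PredictionResult:
    """Evaluate the Volterra series directly from time-domain kernels.

    This is a deliberately independent path from the Laguerre-regressor
    prediction used during estimation (lagged-input tensor contractions
    instead of basis convolutions); the two agree to numerical precision.
    """
    p = bp.values if isinstance(bp, UniformSeries) else np.asarray(bp, float)
    c = co2.values if isinstance(co2, UniformSeries) else np.asarray(co2, float)
    if p.shape != c.shape:
        raise ValueError("bp and co2 must share length")
    fs = bp.fs if isinstance(bp, UniformSeries) else 1.0
    M = kernels.M
    if p.size < M:
        raise ValueError("inputs shorter than kernel memory")
    P = _lag_matrix(p, M)
    C = _lag_matrix(c, M)
    yhat = (k0 + P @ kernels.kP + C @ kernels.kC
            + np.einsum("nm,mk,nk->n", P, kernels.kPP, P)
            + np.einsum("nm,mk,nk->n", C, kernels.kCC, C)
            + np.einsum("nm,mk,nk->n", P, kernels.kPC, C))
    pred = UniformSeries(yhat, fs=fs, label="flow_pred", units="cm/s")
    if observed is None:
        return PredictionResult(predicted=pred, residual=None, nmse=None)
    obs = (observed.values if isinstance(observed, UniformSeries)
           else np.asarray(observed, float))
    resid = obs - yhat
    nmse = _nmse(obs[M - 1:], yhat[M - 1:])
    return PredictionResult(
        predicted=pred,
        residual=UniformSeries(resid, fs=fs, label="residual", units="cm/s"),
        nmse=nmse)


class LaguerreVolterraModel:
    """Dual-input second-order Laguerre-Volterra model of cerebral
    hemodynamics, estimated by ordinary least squares.

    Parameters
    ----------
    flow : UniformSeries or array
        Output (MCAv) series.
    bp, co2 : UniformSeries or array
        Input series; must share length and sampling rate with ``flow``.
    alpha : float
        Laguerre decay parameter in (0, 1).
    n_laguerre : int
        Number of Laguerre functions L per input.
    memory : int, optional
        Kernel memory M in lags; defaults to the decay rule
        :func:`choose_memory`.
    demean_inputs : bool
        Remove the sample mean of BP and CO2 before filtering (the constant
        term k0 absorbs the output mean).  Default True.

    Examples
    --------
    >>> model = LaguerreVolterraModel.from_recording(rec, alpha=0.5, n_laguerre=5)
    >>> res = model.fit()
    >>> res.nmse, res.kernels.kP.shape
    """

    def __init__(self, flow, bp, co2, alpha: float = 0.5, n_laguerre: int = 5,
                 memory: int | None = None, demean_inputs: bool = True):
        def _as_series(x, label):
            if isinstance(x, UniformSeries):
                return x
            return UniformSeries(np.asarray(x, float), fs=1.0, label=label)
        self.flow = _as_series(flow, "flow")
        self.bp = _as_series(bp, "bp")
        self.co2 = _as_series(co2, "co2")
        if not len(self.flow) == len(self.bp) == len(self.co2):
            raise ValueError("flow, bp and co2 must share length")
        self.basis = discrete_laguerre_basis(alpha, n_laguerre, memory)
        self.demean_inputs = demean_inputs
        self.nobs = len(self.flow)
        self.k_params = count_free_parameters(n_laguerre)

    @classmethod
    def from_recording(cls, rec: SubjectRecording, **kwargs):
        return cls(rec.flow, rec.bp, rec.co2, **kwargs)

    @property
    def burn_in(self) -> int:
        return self.basis.M - 1

    def _design(self):
        p = self.bp.values
        c = self.co2.values
        if self.demean_inputs:
            p = p - p.mean()
            c = c - c.mean()
        vP = convolve_basis(self.basis, p)
        vC = convolve_basis(self.basis, c)
        V = build_regressor_matrix(vP, vC, self.basis.M)
        y = self.flow.values[self.burn_in:]
        return V, y

    def fit(self) -> "LaguerreVolterraResults":
        V, y = self._design()
        S, K = V.shape
        if S <= K:
            raise ValueError(
                f"unidentifiable model: {S} samples for {K} parameters")
        if S < 5 * K:
            warnings.warn(
                f"only {S / K:.1f} samples per free parameter (< 5); "
                "kernel estimates may overfit", IdentifiabilityWarning,
                stacklevel=2)
        beta, _, rank, sv = np.linalg.lstsq(V, y, rcond=None)
        if rank < K:
            raise np.linalg.LinAlgError(
                f"rank-deficient regressor matrix (rank {rank} < {K}): "
                "collinear inputs")
        coeffs = KernelCoefficients.from_flat(beta, self.basis.L)
        return LaguerreVolterraResults(self, coeffs, V, y, sv)


class LaguerreVolterraResults:
    """Estimation results: coefficients, reconstructed kernels, fit metrics."""

    def __init__(self, model: LaguerreVolterraModel,
                 coefficients: KernelCoefficients,
                 V: np.ndarray, y: np.ndarray, singular_values: np.ndarray):
        self.model = model
        self.coefficients = coefficients
        self.params = coefficients.to_flat()
        self.kernels = reconstruct_kernels(coefficients, model.basis)
        self.fittedvalues = V @ self.params
        self.resid = y - self.fittedvalues
        self.nmse = _nmse(y, self.fittedvalues)
        self.df_resid = V.shape[0] - V.shape[1]
        self.nobs = V.shape[0]
        self.condition_number = float(singular_values[0] / singular_values[-1])

    @property
    def rss(self) -> float:
        return float(np.sum(self.resid ** 2))

    def bic(self) -> float:
        """Gaussian-residual Bayesian information criterion."""
        n, k = self.nobs, self.model.k_params
        return n * np.log(self.rss / n) + k * np.log(n)

    def prediction(self) -> PredictionResult:
        """Training-data prediction as a :class:`PredictionResult`."""
        fs = self.model.flow.fs
        return PredictionResult(
            predicted=UniformSeries(self.fittedvalues, fs=fs,
                                    label="flow_pred", units="cm/s"),
            residual=UniformSeries(self.resid, fs=fs, label="residual",
                                   units="cm/s"),
            nmse=self.nmse)

    def predict(self, bp=None, co2=None, observed=None) -> PredictionResult:
        """Forward-simulate the fitted model on (possibly new) inputs."""
        bp = self.model.bp if bp is None else bp
        co2 = self.model.co2 if co2 is None else co2
        p = bp.values if isinstance(bp, UniformSeries) else np.asarray(bp, float)
        c = co2.values if isinstance(co2, UniformSeries) else np.asarray(co2, float)
        if self.model.demean_inputs:
            p = p - p.mean()
            c = c - c.mean()
        return predict_output(self.kernels, UniformSeries(p), UniformSeries(c),
                              k0=self.coefficients.k0, observed=observed)

    def summary(self) -> str:
        b = self.model.basis
        lines = [
            "Laguerre-Volterra model (dual input, second order)",
            "=" * 52,
            f"samples (post burn-in): {self.nobs:>6d}",
            f"free parameters:        {self.model.k_params:>6d}",
            f"alpha / L / M:          {b.alpha:g} / {b.L} / {b.M}",
            f"training NMSE:          {self.nmse:>9.4f}",
            f"condition number:       {self.condition_number:>9.3g}",
            f"k0 (constant):          {self.coefficients.k0:>9.4f}",
            "",
            "first-order coefficients (j = 0..L-1):",
            "  beta_P: " + np.array2string(self.coefficients.beta_p,
                                           precision=4),
            "  beta_C: " + np.array2string(self.coefficients.beta_c,
                                           precision=4),
        ]
        return "\n".join(lines)


def estimate_kernels(rec: SubjectRecording, basis: LaguerreBasis,
                     demean_inputs: bool = True):
    """Functional wrapper: fit the model on a recording.

    Returns ``(KernelCoefficients, VolterraKernels, PredictionResult)``.
    """
    model = LaguerreVolterraModel(
        rec.flow, rec.bp, rec.co2, alpha=basis.alpha, n_laguerre=basis.L,
        memory=basis.M, demean_inputs=demean_inputs)
    res = model.fit()
    return res.coefficients, res.kernels, res.prediction()
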