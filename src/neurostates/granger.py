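"""VAR modeling and time-/frequency-domain Granger causality.

The lag regression is segment-aware: data may be one continuous record, a
list of contiguous segments, or an epochs x channels x samples array, and
no regression row ever straddles a segment boundary.  Spectral causality
follows the Geweke formulation: the reduced model's innovation variance is
decomposed, per frequency, into an intrinsic part and the part carried by
the source's (partialized) innovations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as ss

from .errors import EstimationError, InvalidInputError, InvalidParameterError

DEFAULT_FREQ_SPACING = 0.5  # Hz
DEFAULT_MAX_ORDER_MS = 20.0


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _as_segments(X) -> list:
    """Normalize input to a list of (samples x channels) float arrays."""
    if isinstance(X, (list, tuple)):
        segs = [np.asarray(s, dtype=float) for s in X]
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            segs = [X]
        elif X.ndim == 3:  # epochs x channels x samples
            segs = [X[i].T for i in range(X.shape[0])]
        else:
            raise InvalidInputError(f"cannot interpret data with ndim={X.ndim}")
    n_ch = segs[0].shape[1]
    for s in segs:
        if s.ndim != 2 or s.shape[1] != n_ch:
            raise InvalidInputError("all segments must share the channel count")
    return [s - s.mean(axis=0) for s in segs]


def _design(segments, p, offset=None):
    """Stack the lag regression; rows never straddle segment boundaries."""
    offset = p if offset is None else offset
    if offset < p:
        raise InvalidParameterError("offset must be >= model order")
    n_ch = segments[0].shape[1]
    ys, zs = [], []
    for seg in segments:
        n = seg.shape[0]
        if n <= offset:
            continue
        t = np.arange(offset, n)
        ys.append(seg[t])
        zs.append(
            np.concatenate([seg[t - k] for k in range(1, p + 1)], axis=1)
        )
    if not ys:
        raise EstimationError(
            f"no segment long enough for order {p} (offset {offset})"
        )
    Y = np.concatenate(ys, axis=0)
    Z = np.concatenate(zs, axis=0)
    if Y.shape[0] <= n_ch * p:
        raise EstimationError(
            f"{Y.shape[0]} regression rows insufficient for order {p}"
        )
    return Y, Z


# ---------------------------------------------------------------------------
# VAR estimation
# ---------------------------------------------------------------------------

@dataclass
class VarModel:
    """Least-squares VAR: x_t = sum_k A_k x_{t-k} + eps_t."""

    order: int
    coefs: np.ndarray  # (p, n_ch, n_ch)
    sigma: np.ndarray  # innovation covariance
    n_obs: int

    @property
    def n_channels(self):
        return self.coefs.shape[1]

    @property
    def spectral_radius(self) -> float:
        p, n, _ = self.coefs.shape
        comp = np.zeros((n * p, n * p))
        for k in range(p):
            comp[:n, k * n:(k + 1) * n] = self.coefs[k]
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.abs(np.linalg.eigvals(comp)).max())

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def transfer(self, freqs, fs):
        """H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1}, (nf, n, n)."""
        freqs = np.asarray(freqs, dtype=float)
        n = self.n_channels
        omega = 2 * np.pi * freqs / fs
        A_f = np.tile(np.eye(n, dtype=complex), (freqs.size, 1, 1))
        for k in range(self.order):
            phase = np.exp(-1j * omega * (k + 1))
            A_f -= phase[:, None, None] * self.coefs[k][None]
        return np.linalg.inv(A_f)


def fit_var(X, p: int) -> VarModel:
    """OLS fit of a VAR(p) on demeaned, segment-aware data.

    The innovation covariance uses residual denominator n - p.
    """
    if p < 1:
        raise InvalidParameterError("model order p must be >= 1")
    segments = _as_segments(X)
    Y, Z = _design(segments, p)
    coefs_flat, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        raise EstimationError("singular regressor matrix in VAR fit")
    resid = Y - Z @ coefs_flat
    n_rows = Y.shape[0]
    sigma = resid.T @ resid / (n_rows - p)
    n_ch = Y.shape[1]
    coefs = np.stack(
        [coefs_flat[k * n_ch:(k + 1) * n_ch].T for k in range(p)], axis=0
    )
    return VarModel(order=p, coefs=coefs, sigma=sigma, n_obs=n_rows)


def var_autocov(model: VarModel, n_lags: int) -> np.ndarray:
    """Autocovariance sequence Gamma_0..Gamma_{n_lags} implied by the model.

    Gamma_0..Gamma_{p-1} solve the companion-form discrete Lyapunov
    equation; higher lags follow from the Yule-Walker recursion.
    """
    from scipy import linalg as sla

    p, n, _ = model.coefs.shape
    comp = np.zeros((n * p, n * p))
    for k in range(p):
        comp[:n, k * n:(k + 1) * n] = model.coefs[k]
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    big_sigma = np.zeros((n * p, n * p))
    big_sigma[:n, :n] = model.sigma
    gamma_c = sla.solve_discrete_lyapunov(comp, big_sigma)
    gammas = [gamma_c[:n, k * n:(k + 1) * n] for k in range(p)]
    for k in range(p, n_lags + 1):
        g = np.zeros((n, n))
        for i in range(p):
            g += model.coefs[i] @ gammas[k - i - 1]
        gammas.append(g)
    return np.stack(gammas[: n_lags + 1], axis=0)


def whittle_var(autocov: np.ndarray) -> VarModel:
    """Whittle's multivariate Levinson recursion: VAR(q) from Gamma_0..Gamma_q."""
    G = np.asarray(autocov, dtype=float)
    q = G.shape[0] - 1
    n = G.shape[1]
    if q < 1:
        raise InvalidParameterError("need at least one autocovariance lag")
    G0 = G[0]
    A = G[1] @ np.linalg.inv(G0)            # forward coefficients (k, n, n)
    A = A[None]
    B = (G[1].T @ np.linalg.inv(G0))[None]  # backward coefficients
    sig_f = G0 - A[0] @ G[1].T
    sig_b = G0 - B[0] @ G[1]
    for k in range(1, q):
        # delta = G[k+1] - sum_i A_i Gamma_{k-i}
        delta = G[k + 1] - np.einsum("kij,kjl->il", A, G[k::-1][:k])
        A_new = delta @ np.linalg.inv(sig_b)
        B_new = delta.T @ np.linalg.inv(sig_f)
        A_next = np.concatenate([A - A_new @ B[::-1], A_new[None]], axis=0)
        B_next = np.concatenate([B - B_new @ A[::-1], B_new[None]], axis=0)
        A, B = A_next, B_next
        sig_f = sig_f - A_new @ delta.T
        sig_b = sig_b - B_new @ delta
    sig_f = (sig_f + sig_f.T) / 2
    return VarModel(order=q, coefs=A, sigma=sig_f, n_obs=0)


def select_order(
    X,
    fs: float,
    max_order_ms: float = DEFAULT_MAX_ORDER_MS,
    criterion: str = "aic",
) -> int:
    """AIC order selection over p = 1 .. round(max_order_ms * fs / 1000).

    All candidate orders are scored on the common sample that remains after
    dropping ``p_max`` leading samples per segment, so likelihoods are
    comparable; deterministic.
    """
    if criterion.lower() != "aic":
        raise InvalidParameterError("only AIC selection is provided")
    p_max = int(round(max_order_ms * fs / 1000.0))
    if p_max < 1:
        raise InvalidParameterError("max order below one sample")
    segments = _as_segments(X)
    best_p, best_aic = None, np.inf
    for p in range(1, p_max + 1):
        Y, Z = _design(segments, p, offset=p_max)
        coefs_flat, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)
        resid = Y - Z @ coefs_flat
        n = Y.shape[0]
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        k_params = p * Y.shape[1] ** 2
        aic = logdet + 2.0 * k_params / n
        if aic < best_aic:
            best_aic, best_p = aic, p
    if best_p is None:
        raise EstimationError("AIC undefined for every candidate order")
    return best_p


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

@dataclass
class GcResult:
    """One directed interaction with its spectral decomposition."""

    source: int | str
    target: int | str
    conditioning: tuple = ()
    F_time: float = np.nan
    freqs: np.ndarray | None = None
    spectrum: np.ndarray | None = None
    band_means: dict = field(default_factory=dict)
    n_obs: int = 0
    order: int = 0
    p_value: float | None = None
    q_value: float | None = None
    significant: bool | None = None
    floored: bool = False


def _extract(X, idx):
    segments = _as_segments(X)
    return [s[:, list(idx)] for s in segments]


def gc_time_conditional(X, source: int, target: int, conditioning=(), p: int = 1):
    """Time-domain conditional GC, F = ln(det reduced / det full) on the
    target innovation variance; negative estimates are floored at 0.

    Returns (F, floored_flag).
    """
    conditioning = tuple(conditioning)
    if source == target:
        raise InvalidInputError("source and target must differ")
    if source in conditioning or target in conditioning:
        raise InvalidInputError("conditioning set must exclude source and target")
    full_idx = [target, source, *conditioning]
    red_idx = [target, *conditioning]
    full = fit_var(_extract(X, full_idx), p)
    red = fit_var(_extract(X, red_idx), p)
    F = float(np.log(red.sigma[0, 0] / full.sigma[0, 0]))
    if F < 0:
        return 0.0, True
    return F, False


def _partialize(sigma, x_pos, rest):
    """Transform innovations so the source component is uncorrelated with
    the rest; returns (w, sigma_x_partial) with eta'_x = eta_x - w @ eta_rest."""
    s_xr = sigma[x_pos, rest]
    s_rr = sigma[np.ix_(rest, rest)]
    w = np.linalg.solve(s_rr, s_xr)
    sigma_x_partial = sigma[x_pos, x_pos] - s_xr @ w
    return w, sigma_x_partial


def gc_spectral(
    X,
    source: int,
    target: int,
    conditioning=(),
    p: int = 1,
    fs: float = 400.0,
    freqs=None,
    bands=None,
    reduced_lags: int | None = None,
):
    """Geweke frequency-domain (conditional) GC on a frequency grid.

    The full VAR is fitted on (target, source, conditioning).  The reduced
    model on (target, conditioning) is *derived from the full model's
    autocovariance sequence* by the Whittle recursion rather than refitted
    on data, which keeps time- and frequency-domain causality mutually
    consistent (the Geweke integral identity).  The reduced innovations are
    expressed through the full model's transfer function and the share of
    their power carried by the source's partialized innovations gives
    GC(f).  With an empty conditioning set this reduces to classic pairwise
    Geweke causality.

    Returns a :class:`GcResult` with ``spectrum``, ``band_means`` and the
    time-domain ``F_time`` from the same model pair.
    """
    conditioning = tuple(conditioning)
    if source == target:
        raise InvalidInputError("source and target must differ")
    if freqs is None:
        freqs = np.arange(0.0, fs / 2.0 + 1e-9, DEFAULT_FREQ_SPACING)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size and (freqs.min() < 0 or freqs.max() > fs / 2 + 1e-9):
        raise InvalidParameterError("frequency grid must lie within [0, fs/2]")

    full_idx = [target, source, *conditioning]  # y at 0, x at 1, z at 2..
    full = fit_var(_extract(X, full_idx), p)
    if not full.is_stable:
        raise EstimationError(
            f"fitted full VAR unstable (radius {full.spectral_radius:.3f}); "
            "try a lower order"
        )
    if reduced_lags is None:
        # enough lags for the full model's autocovariance to decay to ~1e-8
        rho = min(full.spectral_radius, 0.998)
        decay = int(np.ceil(np.log(1e-8) / np.log(rho))) if rho > 0 else 1
        reduced_lags = int(np.clip(decay, max(4 * p, 20), 2000))
    autocov = var_autocov(full, reduced_lags)
    red_pos_full = [0] + list(range(2, len(full_idx)))
    red = whittle_var(autocov[np.ix_(np.arange(reduced_lags + 1), red_pos_full, red_pos_full)])

    n = len(full_idx)
    rest = [0] + list(range(2, n))  # everything but the source
    H = full.transfer(freqs, fs)
    G = red.transfer(freqs, fs)

    # embed the reduced transfer into the full variable ordering
    G_t = np.tile(np.eye(n, dtype=complex), (freqs.size, 1, 1))
    G_t[np.ix_(np.arange(freqs.size), rest, rest)] = G
    Q = np.linalg.solve(G_t, H)

    w, sigma_x_partial = _partialize(full.sigma, 1, rest)
    # Q' = Q P^{-1}; P^{-1} adds w-weighted source column into rest columns
    Qp = Q.copy()
    Qp[:, :, rest] += Q[:, :, [1]] * w[None, None, :]

    sigma_rest = full.sigma[np.ix_(rest, rest)]
    row = Qp[:, 0, :][:, rest]  # target row, non-source columns
    intrinsic = np.real(np.einsum("fi,ij,fj->f", row, sigma_rest, row.conj()))
    source_part = np.abs(Qp[:, 0, 1]) ** 2 * sigma_x_partial
    # total reduced-innovation power decomposes into intrinsic + source
    # parts, so GC(f) = ln(1 + source/intrinsic) is nonnegative pointwise
    with np.errstate(divide="ignore", invalid="ignore"):
        spectrum = np.log1p(source_part / intrinsic)
    spectrum = np.nan_to_num(spectrum, nan=0.0, posinf=0.0)

    F = float(np.log(red.sigma[0, 0] / full.sigma[0, 0]))
    floored = F < 0
    result = GcResult(
        source=source,
        target=target,
        conditioning=conditioning,
        F_time=max(F, 0.0),
        freqs=freqs,
        spectrum=spectrum,
        n_obs=full.n_obs,
        order=p,
        floored=floored,
    )
    if bands:
        for name, (lo, hi) in bands.items():
            sel = (freqs >= lo) & (freqs < hi)
            result.band_means[name] = float(spectrum[sel].mean()) if sel.any() else np.nan
    return result


def spectral_to_time(result: GcResult, fs: float) -> float:
    """Geweke integral: mean of GC(f) over [0, Nyquist] equals F_time."""
    freqs, spec = result.freqs, result.spectrum
    return float(np.trapezoid(spec, freqs) / (freqs[-1] - freqs[0]))


def gc_significance(results, Q: float = 0.05, n_lags: int | None = None):
    """Asymptotic chi2 p-values for n*F with Benjamini-Hochberg adjustment.

    Mutates each GcResult's ``p_value`` / ``q_value`` in place and returns
    the list.  Significant iff q < Q.
    """
    results = list(results)
    ps = []
    for r in results:
        df = n_lags if n_lags is not None else r.order
        stat = r.n_obs * r.F_time
        ps.append(float(ss.chi2.sf(stat, df)))
    qs = ss.false_discovery_control(ps, method="bh")
    for r, pv, qv in zip(results, ps, qs):
        r.p_value = pv
        r.q_value = float(qv)
        r.significant = bool(qv < Q)
    return results


def gc_all_directions(
    X,
    p: int,
    fs: float,
    channel_names=None,
    conditional: bool = True,
    bands=None,
):
    """Every ordered channel pair; conditional on all remaining channels."""
    segments = _as_segments(X)
    n_ch = segments[0].shape[1]
    names = channel_names or list(range(n_ch))
    out = []
    for tgt in range(n_ch):
        for src in range(n_ch):
            if src == tgt:
                continue
            cond = tuple(c for c in range(n_ch) if c not in (src, tgt)) if conditional else ()
            r = gc_spectral(segments, src, tgt, cond, p=p, fs=fs, bands=bands)
            r.source = names[src]
            r.target = names[tgt]
            r.conditioning = tuple(names[c] for c in cond)
            out.append(r)
    return out
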