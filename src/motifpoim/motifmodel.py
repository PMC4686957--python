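"""Probabilistic positional motifs (PPMs) and the motifPOIM inverse problem.

A PPM m_k = (r, μ, σ) is a 4×k column-stochastic PWM ``r`` together with a
Gaussian start-position belief: the motif starts at position i with density
N(i; μ, σ²). It induces a weight vector over positional k-mers,

    v_{(z,i)}(m_k) = (2πσ²)^{−1/2} · exp(−(i−μ)²/2σ²) · Π_l r[z_l, l],

and therefore — exactly like an SVM weight vector does — a POIM, the
*motifPOIM* R(m_k). Long motifs (k > k̃) are handled by decomposing the PPM
into D = k − k̃ + 1 overlapping SubPPMs of small order k̃ ∈ {2, 3} and summing
their motifPOIMs, so the reconstruction always lives at the cheap order k̃.

Each SubPPM motifPOIM entry is an inner product of two small matrices
(an inner-product evaluation): a position-independent *dependency matrix* A(y)
holding the conditional-probability terms for every oligomer z at every
overlap offset of a fixed k̃-mer y, and a per-position weight matrix C^j
holding the v-weights. Motif recovery then minimizes

    f = ½ Σ_{y,j} ( Σ_t λ_t R_{y,j}(m_t) − Q_{k̃,y,j} )²

over (r, μ, σ, λ) of all candidate PPMs jointly, with box bounds
ε ≤ r ≤ 1, 1 ≤ μ ≤ L−k+1, ε ≤ σ ≤ k, 0 ≤ λ ≤ W, using L-BFGS-B with
analytic gradients. The simplex constraint on PWM columns is enforced by
renormalizing the raw box variables inside every objective evaluation, so the
solver sees a smooth unconstrained-on-the-simplex landscape while the columns
always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .poim import Poim
from .wdsvm import encode

DEFAULT_EPS = 1e-3
DEFAULT_W = 1000.0
DEFAULT_MAX_ITER = 500
DEFAULT_TOL = 1e-8


@dataclass
class Ppm:
    """Candidate motif: PWM ``r`` (rows A,C,G,T), start μ, spread σ, weight λ."""

    r: np.ndarray  # (4, k), column-stochastic
    mu: float
    sigma: float
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        if self.r.ndim != 2 or self.r.shape[0] != 4:
            raise ValueError("PWM must be 4 x k")
        sums = self.r.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError(f"PWM columns must sum to 1 (got {sums})")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mu < 1:
            raise ValueError("mu must be >= 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def k(self) -> int:
        return self.r.shape[1]


@dataclass
class SubPpm:
    """Length-k̃ slice of a parent PPM, shifted to μ̃ = μ + offset."""

    r: np.ndarray  # (4, ktilde)
    mu: float
    sigma: float
    offset: int

    @property
    def ktilde(self) -> int:
        return self.r.shape[1]


@dataclass
class FitSpec:
    """Configuration of the motifPOIM fit.

    Attributes
    ----------
    K : tuple of int
        Motif lengths to fit.
    T : tuple of int
        Number of PPMs per length (aligned with K).
    ktilde : int
        POIM order used for reconstruction (2 or 3).
    eps, W : float
        Lower bound for PWM entries / σ, upper bound for λ.
    max_iter : int
        L-BFGS-B iteration cap.
    tol : float
        Solver convergence tolerance (ftol and gtol).
    per_length_residual : bool
        If True, one residual against Q per motif length (the printed
        grouping); default sums all weighted motifPOIMs into one residual.
    simplex_projection : bool
        If True (default), renormalize PWM columns to the probability simplex
        inside every objective evaluation, so the column-sum constraint holds
        at every function evaluation. If False, the box-constrained solver
        works on raw entries in [ε, 1] — a column may then scale uniformly to
        modulate its motifPOIM magnitude without changing its letter
        proportions — and the columns are normalized once on return.
    seed : int
        Seed for random restarts.
    """

    K: tuple[int, ...]
    T: tuple[int, ...] = ()
    ktilde: int = 2
    eps: float = DEFAULT_EPS
    W: float = DEFAULT_W
    max_iter: int = DEFAULT_MAX_ITER
    tol: float = DEFAULT_TOL
    per_length_residual: bool = False
    simplex_projection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.T:
            self.T = tuple(1 for _ in self.K)
        if self.ktilde not in (2, 3):
            raise ValueError("ktilde must be 2 or 3")
        if self.K and self.ktilde > min(self.K):
            raise ValueError("ktilde must not exceed the smallest motif length")
        if len(self.T) != len(self.K):
            raise ValueError("T must align with K")


@dataclass
class FitResult:
    ppms: list[Ppm]
    f_opt: float
    n_iter: int
    converged: bool
    message: str


def gaussian_position(p, mu: float, sigma: float) -> np.ndarray:
    """Positional factor (2πσ²)^{−1/2} exp(−(p−μ)²/2σ²)."""
    p = np.asarray(p, dtype=np.float64)
    z = (p - mu) / sigma
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sigma)


def _path_probs(r: np.ndarray) -> np.ndarray:
    """Π_l r[z_l, l] for all 4^k oligomer codes z (code-major order)."""
    out = np.ones(1)
    for col in range(r.shape[1]):
        out = np.kron(out, r[:, col])
    return out


def motif_weight(m: Ppm, z, i: int) -> float:
    """Motif weight v_{(z,i)}(m): Gaussian position factor times PWM path."""
    zc = encode(z) if isinstance(z, str) else np.asarray(z)
    if len(zc) != m.k:
        raise ValueError(f"oligomer length {len(zc)} != motif length {m.k}")
    path = float(np.prod(m.r[zc, np.arange(m.k)]))
    return float(gaussian_position(i, m.mu, m.sigma)) * path


def subppms(m: Ppm, ktilde: int) -> list[SubPpm]:
    """The D = k − k̃ + 1 consecutive length-k̃ slices of a PPM."""
    if ktilde > m.k:
        raise ValueError("ktilde exceeds motif length")
    return [
        SubPpm(r=m.r[:, d : d + ktilde], mu=m.mu + d, sigma=m.sigma, offset=d)
        for d in range(m.k - ktilde + 1)
    ]


_A_TENSOR_CACHE: dict[int, np.ndarray] = {}


def dependency_tensor(ktilde: int) -> np.ndarray:
    """A[y, z, o] over all k̃-mers y, z and the 2(k̃−1)+1 overlap offsets.

    Offset index o corresponds to δ = o − (k̃−1) ∈ [−(k̃−1), k̃−1]; entry
    (4^c − 1)/4^k̃ when (z, reference+δ) is compatible with (y, reference),
    −1/4^k̃ otherwise. Position independent, computed once per k̃.
    """
    if ktilde in _A_TENSOR_CACHE:
        return _A_TENSOR_CACHE[ktilde]
    nk = 4**ktilde
    codes = np.arange(nk, dtype=np.int64)
    A = np.empty((nk, nk, 2 * ktilde - 1))
    for o, delta in enumerate(range(-(ktilde - 1), ktilde)):
        a = max(0, delta)  # overlap in y coordinates (0-based)
        b = min(ktilde - 1, delta + ktilde - 1)
        c = b - a + 1
        ysub = (codes >> (2 * (ktilde - 1 - b))) & ((1 << 2 * c) - 1)
        zsub = (codes >> (2 * (ktilde - 1 - (b - delta)))) & ((1 << 2 * c) - 1)
        comp = ysub[:, None] == zsub[None, :]
        A[:, :, o] = np.where(comp, (4.0**c - 1.0) / 4.0**ktilde, -1.0 / 4.0**ktilde)
    _A_TENSOR_CACHE[ktilde] = A
    return A


def dependency_matrix(y: int, ktilde: int) -> np.ndarray:
    """A(y): 4^k̃ × (2(k̃−1)+1) probability-term matrix for one k̃-mer y."""
    return dependency_tensor(ktilde)[y].copy()


def sub_weight_table(sub: SubPpm, L: int) -> np.ndarray:
    """V[z, p] = v_{(z, p+1)}(sub) for all codes z and starts p+1 ∈ 1..L−k̃+1."""
    ncols = L - sub.ktilde + 1
    g = gaussian_position(np.arange(1, ncols + 1), sub.mu, sub.sigma)
    r = sub.r / sub.r.sum(axis=0, keepdims=True)
    return _path_probs(r)[:, None] * g[None, :]


def weight_matrix(y: int, j: int, sub: SubPpm, L: int) -> np.ndarray:
    """C^j(y): weights of all oligomers overlapping position j (zero off-sequence)."""
    kt = sub.ktilde
    ncols = L - kt + 1
    if not 1 <= j <= ncols:
        raise ValueError(f"position {j} outside 1..{ncols}")
    V = sub_weight_table(sub, L)
    C = np.zeros((4**kt, 2 * kt - 1))
    for o, delta in enumerate(range(-(kt - 1), kt)):
        p = j + delta
        if 1 <= p <= ncols:
            C[:, o] = V[:, p - 1]
    return C


def _reconstruct_sub(V: np.ndarray, ktilde: int) -> np.ndarray:
    """R[y, j] = Σ_{z,δ} A[y,z,δ] V[z, j+δ] via 2k̃−1 small matmuls."""
    A = dependency_tensor(ktilde)
    ncols = V.shape[1]
    pad = ktilde - 1
    Vp = np.zeros((V.shape[0], ncols + 2 * pad))
    Vp[:, pad : pad + ncols] = V
    R = np.zeros((4**ktilde, ncols))
    for o in range(2 * ktilde - 1):
        delta = o - pad
        R += A[:, :, o] @ Vp[:, pad + delta : pad + delta + ncols]
    return R


def _adjoint_sub(E: np.ndarray, ktilde: int) -> np.ndarray:
    """U[z, p] = Σ_{y,δ} A[y,z,δ] E[y, p−δ] — adjoint of :func:`_reconstruct_sub`."""
    A = dependency_tensor(ktilde)
    ncols = E.shape[1]
    pad = ktilde - 1
    Ep = np.zeros((E.shape[0], ncols + 2 * pad))
    Ep[:, pad : pad + ncols] = E
    U = np.zeros((4**ktilde, ncols))
    for o in range(2 * ktilde - 1):
        delta = o - pad
        U += A[:, :, o].T @ Ep[:, pad - delta : pad - delta + ncols]
    return U


def truncation_mask(m: Ppm, ktilde: int, L: int) -> np.ndarray:
    """Columns inside the union of SubPPM 3σ confidence windows (bool, len L−k̃+1)."""
    ncols = L - ktilde + 1
    mask = np.zeros(ncols, dtype=bool)
    for d in range(m.k - ktilde + 1):
        mu_d = m.mu + d
        lo = max(1, int(np.floor(mu_d - 3.0 * m.sigma)))
        hi = min(ncols, int(np.ceil(mu_d + 3.0 * m.sigma)))
        if lo <= hi:
            mask[lo - 1 : hi] = True
    return mask


def reconstruct_motifpoim(
    m: Ppm, ktilde: int, L: int, truncate: bool = True
) -> np.ndarray:
    """motifPOIM R(m) of order k̃: sum of the SubPPM motifPOIMs, λ-free.

    With ``truncate`` (default) columns outside the union of the SubPPMs'
    [μ̃−3σ, μ̃+3σ] windows (rounded outward) are set to zero — the 99.7%-mass
    confidence truncation.
    """
    R = np.zeros((4**ktilde, L - ktilde + 1))
    for sub in subppms(m, ktilde):
        R += _reconstruct_sub(sub_weight_table(sub, L), ktilde)
    if truncate:
        R[:, ~truncation_mask(m, ktilde, L)] = 0.0
    return R


def motifpoim_reduced_sum(m: Ppm, ktilde: int, L: int) -> np.ndarray:
    """Reduced two-set summation form (compatible + dependent-incompatible POs)."""
    from .poim import conditional_probability

    ncols = L - ktilde + 1
    R = np.zeros((4**ktilde, ncols))
    for sub in subppms(m, ktilde):
        V = sub_weight_table(sub, L)
        for y in range(4**ktilde):
            for j in range(1, ncols + 1):
                acc = 0.0
                for i in range(max(1, j - ktilde + 1), min(ncols, j + ktilde - 1) + 1):
                    for z in range(4**ktilde):
                        p = conditional_probability(z, i, ktilde, y, j, ktilde)
                        acc += V[z, i - 1] * (p - 0.25**ktilde)
                R[y, j - 1] += acc
    return R


def motifpoim_bruteforce(m: Ppm, ktilde: int, L: int) -> np.ndarray:
    """Enumeration oracle: conditional means of s̄ over all 4^L sequences."""
    from .wdsvm import window_codes

    if L > 8:
        raise ValueError("brute force refuses L > 8")
    n = 4**L
    grid = np.array(
        np.unravel_index(np.arange(n), (4,) * L), dtype=np.uint8
    ).T.copy()
    wk = window_codes(grid, ktilde)
    ncols = L - ktilde + 1
    R = np.zeros((4**ktilde, ncols))
    for sub in subppms(m, ktilde):
        V = sub_weight_table(sub, L)
        sbar = V[wk, np.arange(ncols)[None, :]].sum(axis=1)
        mean = float(np.mean(sbar))
        for j0 in range(ncols):
            sums = np.bincount(wk[:, j0], weights=sbar, minlength=4**ktilde)
            counts = np.bincount(wk[:, j0], minlength=4**ktilde)
            R[:, j0] += sums / counts - mean
    return R


# ---------------------------------------------------------------------------
# objective and fit
# ---------------------------------------------------------------------------


def _groups(ppms: list[Ppm], per_length: bool) -> list[list[int]]:
    if not per_length:
        return [list(range(len(ppms)))]
    by_k: dict[int, list[int]] = {}
    for t, m in enumerate(ppms):
        by_k.setdefault(m.k, []).append(t)
    return list(by_k.values())


def objective(
    ppms: list[Ppm],
    Q: Poim,
    per_length_residual: bool = False,
    columns: np.ndarray | None = None,
) -> float:
    """f = ½ Σ_{y,j} (Σ_t λ_t R_{y,j}(m_t) − Q_{y,j})² over valid columns.

    ``columns`` optionally restricts the residual to a boolean column mask
    (used when fitting one window of a long POIM).
    """
    ktilde = Q.order
    mask = np.ones(Q.values.shape[1], dtype=bool) if columns is None else columns
    f = 0.0
    for group in _groups(ppms, per_length_residual):
        M = np.zeros_like(Q.values)
        for t in group:
            M += ppms[t].lam * reconstruct_motifpoim(
                ppms[t], ktilde, Q.L, truncate=False
            )
        E = (M - Q.values)[:, mask]
        f += 0.5 * float(np.sum(E * E))
    return f


def _pack(ppms: list[Ppm]) -> np.ndarray:
    parts = []
    for m in ppms:
        parts.extend([m.r.ravel(), [m.mu, m.sigma, m.lam]])
    return np.concatenate([np.asarray(p, dtype=np.float64) for p in parts])


def _unpack_raw(x: np.ndarray, ks: list[int]):
    out, pos = [], 0
    for k in ks:
        raw = x[pos : pos + 4 * k].reshape(4, k)
        mu, sigma, lam = x[pos + 4 * k : pos + 4 * k + 3]
        out.append((raw, mu, sigma, lam))
        pos += 4 * k + 3
    return out


def _value_and_grad(
    x: np.ndarray,
    ks: list[int],
    Q: Poim,
    groups: list[list[int]],
    mask: np.ndarray,
    normalize: bool = False,
):
    ktilde = Q.order
    params = _unpack_raw(x, ks)
    ncols = Q.values.shape[1]
    p_axis = np.arange(1, ncols + 1, dtype=np.float64)

    # forward: per-PPM motifPOIMs and cached per-sub quantities
    cache = []
    for raw, mu, sigma, lam in params:
        if normalize:
            S = raw.sum(axis=0)
            r = raw / S
        else:
            S = np.ones(raw.shape[1])
            r = raw
        subs = []
        Rt = np.zeros((4**ktilde, ncols))
        for d in range(r.shape[1] - ktilde + 1):
            g = gaussian_position(p_axis, mu + d, sigma)
            pi = _path_probs(r[:, d : d + ktilde])
            V = pi[:, None] * g[None, :]
            Rt += _reconstruct_sub(V, ktilde)
            subs.append((g, pi))
        cache.append((r, S, subs, Rt))

    f = 0.0
    grad = np.zeros_like(x)
    offsets = np.cumsum([0] + [4 * k + 3 for k in ks])
    for group in groups:
        M = np.zeros((4**ktilde, ncols))
        for t in group:
            M += params[t][3] * cache[t][3]
        E = M - Q.values
        E[:, ~mask] = 0.0
        f += 0.5 * float(np.sum(E * E))
        U = _adjoint_sub(E, ktilde)  # ⟨E, G(V)⟩ = ⟨U, V⟩ for every V
        for t in group:
            raw, mu, sigma, lam = params[t]
            r, S, subs, Rt = cache[t]
            k = ks[t]
            base = offsets[t]
            dlam = float(np.sum(E * Rt))
            dmu = 0.0
            dsigma = 0.0
            grad_norm = np.zeros_like(r)
            for d, (g, pi) in enumerate(subs):
                mu_d = mu + d
                Ug = U @ g  # Σ_p U[z,p] g(p), length 4^k̃
                P = pi @ U  # Σ_z U[z,p] π(z), length ncols
                zc = (p_axis - mu_d) / sigma
                Pg = P * g
                dmu += float(np.sum(Pg * zc)) / sigma
                dsigma += float(np.sum(Pg * (zc * zc - 1.0))) / sigma
                t_vec = Ug * pi
                cube = t_vec.reshape((4,) * ktilde)
                for q in range(ktilde):
                    axes = tuple(a for a in range(ktilde) if a != q)
                    by_base = cube.sum(axis=axes) if axes else cube
                    col = d + q
                    grad_norm[:, col] += by_base / r[:, col]
            if normalize:
                # chain rule through the per-column renormalization r = raw / S
                dot = np.sum(grad_norm * r, axis=0)
                grad_raw = (grad_norm - dot[None, :]) / S[None, :]
            else:
                grad_raw = grad_norm
            grad[base : base + 4 * k] += lam * grad_raw.ravel()
            grad[base + 4 * k] += lam * dmu
            grad[base + 4 * k + 1] += lam * dsigma
            grad[base + 4 * k + 2] += dlam
    return f, grad


def objective_gradient(
    ppms: list[Ppm],
    Q: Poim,
    per_length_residual: bool = False,
    columns: np.ndarray | None = None,
) -> tuple[float, list[dict[str, np.ndarray]]]:
    """Analytic (f, gradients) at the given PPMs; gradients per PPM as dicts."""
    ks = [m.k for m in ppms]
    mask = np.ones(Q.values.shape[1], dtype=bool) if columns is None else columns
    x = _pack(ppms)
    f, g = _value_and_grad(x, ks, Q, _groups(ppms, per_length_residual), mask)
    out = []
    pos = 0
    for k in ks:
        out.append(
            {
                "r": g[pos : pos + 4 * k].reshape(4, k).copy(),
                "mu": g[pos + 4 * k],
                "sigma": g[pos + 4 * k + 1],
                "lam": g[pos + 4 * k + 2],
            }
        )
        pos += 4 * k + 3
    return f, out


def fit(
    Q: Poim,
    spec: FitSpec,
    init: list[Ppm],
    columns: np.ndarray | None = None,
) -> FitResult:
    """Box-constrained L-BFGS-B minimization of the motifPOIM objective.

    ``init`` supplies one PPM per optimization slot; lengths must match the
    expansion of (spec.K, spec.T). Returns the fitted PPMs with exactly
    renormalized PWM columns plus the final objective value and iteration
    count.
    """
    expected = [k for k, t in zip(spec.K, spec.T) for _ in range(t)]
    ks = [m.k for m in init]
    if sorted(ks) != sorted(expected):
        raise ValueError(f"init lengths {ks} do not match spec {expected}")
    if Q.order != spec.ktilde:
        raise ValueError("POIM order must equal spec.ktilde")
    mask = np.ones(Q.values.shape[1], dtype=bool) if columns is None else columns
    groups = _groups(init, spec.per_length_residual)
    L = Q.L

    x0 = _pack(init)
    bounds = []
    for m in init:
        bounds.extend([(spec.eps, 1.0)] * (4 * m.k))
        bounds.append((1.0, max(1.0, L - m.k + 1)))
        bounds.append((spec.eps, float(m.k)))
        bounds.append((0.0, spec.W))
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    x0 = np.clip(x0, lo, hi)

    res = minimize(
        _value_and_grad,
        x0,
        args=(ks, Q, groups, mask, spec.simplex_projection),
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"maxiter": spec.max_iter, "ftol": spec.tol, "gtol": spec.tol},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"non-finite objective at final iterate: {res.message}")
    fitted = []
    for raw, mu, sigma, lam in _unpack_raw(res.x, ks):
        r = raw / raw.sum(axis=0, keepdims=True)
        fitted.append(Ppm(r=r, mu=float(mu), sigma=float(sigma), lam=float(lam)))
    return FitResult(
        ppms=fitted,
        f_opt=float(res.fun),
        n_iter=int(res.nit),
        converged=bool(res.success),
        message=str(res.message),
    )


def matched_lambda(Q: Poim, ppm: Ppm, floor_frac: float = 0.01) -> float:
    """Least-squares λ for one PPM against Q, floored away from zero.

    λ is scale-dependent (it bridges the PPM's unit-mass motifPOIM and the
    SVM's POIM magnitudes), so a fixed starting value can place the first
    iterate so far from the data scale that the solver parks λ at a bound.
    The non-negative least-squares scale ⟨Q, R⟩/⟨R, R⟩ starts the search at
    the right order of magnitude; the floor (a small fraction of ‖Q‖/‖R‖)
    keeps the gradient alive when the initial shape anti-correlates with Q.
    """
    R = reconstruct_motifpoim(ppm, Q.order, Q.L, truncate=False)
    rr = float(np.sum(R * R))
    if rr <= 0:
        return ppm.lam
    lam = float(np.sum(Q.values * R) / rr)
    floor = floor_frac * float(np.sqrt(np.sum(Q.values**2) / rr))
    return max(lam, floor)


def random_init_ppm(
    k: int, mu: float, rng: np.random.Generator, sigma: float = 1.0, lam: float = 1.0
) -> Ppm:
    """PPM with PWM columns drawn from a flat Dirichlet (random-restart mode)."""
    r = rng.dirichlet(np.ones(4), size=k).T
    r = np.clip(r, DEFAULT_EPS, 1.0)
    r /= r.sum(axis=0, keepdims=True)
    return Ppm(r=r, mu=mu, sigma=sigma, lam=lam)
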