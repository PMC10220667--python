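"""Low-rank completion of a single masked block.

A block is a channels x time matrix in which a subset of entries is marked
corrupted (eye blinks, motion bursts, amplifier saturation ...).  Under the
hypothesis that the underlying multichannel signal is (locally) low rank —
neural trajectories unfold on a manifold of dimension far below the channel
count — the corrupted entries can be inferred from the observed ones by
minimizing, over orthonormal factor pairs ``(X, Y)``, the observed-entry
misfit

    F(X, Y) = min_S || P_Omega(M) - P_Omega(X S Y^T) ||_F

where ``P_Omega`` keeps only observed entries and the r x r core ``S`` is the
exact least-squares solution for the given pair.  The solver follows the
OptSpace recipe: trim over-represented rows/columns, initialize from a
rescaled truncated SVD of the zero-filled matrix, then run projected
steepest descent on the factor pair with QR retraction and a backtracking
(Armijo) line search.

The module exposes the individual steps (:func:`zero_fill`, :func:`trim`,
:func:`svd_initialize`, :func:`solve_core`, :func:`cost`) as plain
functions, the one-call :func:`complete`, and a model-style wrapper
:class:`LowRankCompletion` whose :meth:`~LowRankCompletion.fit` returns a
:class:`CompletionResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import (
    DataError,
    InfeasibleBlockError,
    InvalidRankError,
    SingularSystemError,
)

__all__ = [
    "MaskedMatrix",
    "Factorization",
    "CompletionResult",
    "LowRankCompletion",
    "zero_fill",
    "trim",
    "svd_initialize",
    "solve_core",
    "cost",
    "complete",
]

_ORTHO_TOL = 1e-8


@dataclass
class MaskedMatrix:
    """A channels x time block with an observed/corrupted partition.

    Parameters
    ----------
    values : ndarray, shape (C, Tk)
        Signal values (muV).  Entries at unobserved positions are ignored.
    mask : ndarray of bool, shape (C, Tk)
        ``True`` where the entry is observed (usable), ``False`` where it
        is corrupted and must be inferred.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if self.values.ndim != 2:
            raise ValueError("MaskedMatrix requires 2-D arrays")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def severity(self) -> float:
        """Percent of entries that are corrupted, in [0, 100]."""
        return 100.0 * (self.mask.size - self.mask.sum()) / self.mask.size

    def missing_rows(self) -> list[int]:
        """Rows with no observed entry (unrecoverable without removal)."""
        return np.flatnonzero(~self.mask.any(axis=1)).tolist()

    def missing_cols(self) -> list[int]:
        """Columns with no observed entry."""
        return np.flatnonzero(~self.mask.any(axis=0)).tolist()

    def is_completable(self) -> bool:
        """Every row and column has at least one observed entry."""
        return not self.missing_rows() and not self.missing_cols()

    def copy(self) -> "MaskedMatrix":
        return MaskedMatrix(self.values.copy(), self.mask.copy())


@dataclass
class Factorization:
    """Orthonormal factor pair plus core: model = left @ core @ right.T."""

    left: np.ndarray   # C x r, orthonormal columns
    core: np.ndarray   # r x r
    right: np.ndarray  # Tk x r, orthonormal columns

    @property
    def rank(self) -> int:
        return self.left.shape[1]

    def model(self) -> np.ndarray:
        """The dense low-rank reconstruction over all entries."""
        return self.left @ self.core @ self.right.T

    def check_orthonormal(self, tol: float = _ORTHO_TOL) -> bool:
        r = self.rank
        return (
            np.allclose(self.left.T @ self.left, np.eye(r), atol=tol)
            and np.allclose(self.right.T @ self.right, np.eye(r), atol=tol)
        )


@dataclass
class CompletionResult:
    """Outcome of fitting a low-rank model to a masked block.

    ``completed`` is the model evaluated over *all* entries (the low-rank
    regeneration of the block); observed entries of the input are therefore
    also replaced by their model values.
    """

    completed: np.ndarray
    factorization: Factorization
    iterations: int
    final_cost: float
    converged: bool
    cost_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    infeasible_rows: list = field(default_factory=list)
    infeasible_cols: list = field(default_factory=list)

    def summary(self) -> str:
        f = self.factorization
        lines = [
            "Low-rank completion results",
            "===========================",
            f"block shape:      {f.left.shape[0]} x {f.right.shape[0]}",
            f"rank:             {f.rank}",
            f"iterations:       {self.iterations}",
            f"converged:        {self.converged}",
            f"final cost:       {self.final_cost:.6g}",
        ]
        if self.infeasible_rows or self.infeasible_cols:
            lines.append(f"infeasible rows:  {self.infeasible_rows}")
            lines.append(f"infeasible cols:  {self.infeasible_cols}")
        return "\n".join(lines)


def zero_fill(block: MaskedMatrix) -> np.ndarray:
    """Replace corrupted entries with zeros (the matrix ``M^E``)."""
    return np.where(block.mask, block.values, 0.0)


def trim(block: MaskedMatrix, degree_factor: float = 2.0) -> MaskedMatrix:
    """Zero out over-represented rows and columns before the spectral step.

    A row (column) is over-represented when its observed-entry count exceeds
    ``degree_factor`` times the mean row (column) count; its entries are set
    to zero and marked unobserved in a copy.  Over-represented lines would
    otherwise dominate the leading singular vectors of the zero-filled
    matrix and bias the subspace estimate.
    """
    if degree_factor <= 0:
        raise ValueError("degree_factor must be > 0")
    out = block.copy()
    row_deg = block.mask.sum(axis=1)
    col_deg = block.mask.sum(axis=0)
    heavy_rows = row_deg > degree_factor * row_deg.mean()
    heavy_cols = col_deg > degree_factor * col_deg.mean()
    out.values[heavy_rows, :] = 0.0
    out.mask[heavy_rows, :] = False
    out.values[:, heavy_cols] = 0.0
    out.mask[:, heavy_cols] = False
    return out


def _fix_svd_signs(u: np.ndarray, v: np.ndarray):
    """Resolve SVD sign ambiguity: largest-|.| entry of each left singular
    vector made positive, for reproducible factorizations."""
    for k in range(u.shape[1]):
        i = np.argmax(np.abs(u[:, k]))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            v[:, k] = -v[:, k]
    return u, v


def svd_initialize(
    block: MaskedMatrix, rank: int, degree_factor: float = 2.0
) -> Factorization:
    """Spectral initialization: rank-r truncated SVD of the trimmed,
    zero-filled matrix, rescaled by (C*Tk)/|Omega|.

    The rescaling compensates the downward bias of singular values caused
    by zero-filling under (approximately) uniform sampling of the observed
    set, so the initial core is on the right scale.
    """
    c, tk = block.shape
    if rank < 1 or rank > min(c, tk):
        raise InvalidRankError(
            f"rank {rank} invalid for a {c} x {tk} block"
        )
    trimmed = trim(block, degree_factor)
    n_obs = trimmed.n_observed
    if n_obs == 0:
        raise InfeasibleBlockError(trimmed.missing_rows(), trimmed.missing_cols())
    scale = (c * tk) / n_obs
    u, s, vt = np.linalg.svd(zero_fill(trimmed), full_matrices=False)
    u, v = _fix_svd_signs(u[:, :rank].copy(), vt[:rank].T.copy())
    return Factorization(left=u, core=np.diag(s[:rank] * scale), right=v)


def _core_normal_system(left, right, block, chunk=65536):
    """Accumulate the r^2 x r^2 normal equations of the observed-entry
    least-squares problem for the core matrix, chunked to bound memory."""
    r = left.shape[1]
    rows, cols = np.nonzero(block.mask)
    vals = block.values[rows, cols]
    g = np.zeros((r * r, r * r))
    rhs = np.zeros(r * r)
    for start in range(0, rows.size, chunk):
        sl = slice(start, start + chunk)
        # design row for entry (i,j): outer(X[i], Y[j]) flattened
        b = (left[rows[sl]][:, :, None] * right[cols[sl]][:, None, :]).reshape(
            -1, r * r
        )
        g += b.T @ b
        rhs += b.T @ vals[sl]
    return g, rhs, rows.size


def _solve_core_direct(left, right, block, block_index=None):
    r = left.shape[1]
    g, rhs, n_obs = _core_normal_system(left, right, block)
    s_flat, _, rank_g, _ = scipy.linalg.lstsq(g, rhs, lapack_driver="gelsd")
    if rank_g < r * r:
        raise SingularSystemError(
            f"core system rank {rank_g} < {r * r}: observed pattern too sparse",
            block_index,
        )
    return s_flat.reshape(r, r)


def solve_core(
    left: np.ndarray,
    right: np.ndarray,
    block: MaskedMatrix,
    block_index=None,
    warm_start: np.ndarray | None = None,
) -> np.ndarray:
    """Exact least-squares core: S = argmin_S ||P_Omega(M - X S Y^T)||_F.

    The problem is linear in the r^2 unknowns of S.  Small systems are
    solved through their dense normal equations; larger ones by conjugate
    gradients on the masked normal operator S -> X^T P_Omega(X S Y^T) Y,
    which avoids assembling the r^2 x r^2 matrix (the operator is the
    identity for a full mask, so CG is fast whenever observation density
    is high).  Raises :class:`SingularSystemError` when the design is rank
    deficient (too few observed entries to pin down the core).
    """
    r = left.shape[1]
    if right.shape[1] != r:
        raise ValueError("left and right factors must share the rank")
    n_obs = block.n_observed
    if n_obs < r * r:
        raise SingularSystemError(
            f"{n_obs} observed entries cannot determine a {r} x {r} core",
            block_index,
        )
    if r <= 4:
        return _solve_core_direct(left, right, block, block_index)

    mask = block.mask
    me = np.where(mask, block.values, 0.0)

    def normal_op(s):
        return left.T @ np.where(mask, left @ s @ right.T, 0.0) @ right

    rhs = left.T @ me @ right
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm == 0.0:
        return np.zeros((r, r))
    if warm_start is not None and warm_start.shape == (r, r):
        s = warm_start.copy()
        resid = rhs - normal_op(s)
    else:
        s = np.zeros((r, r))
        resid = rhs.copy()
    p = resid.copy()
    rs = float(np.sum(resid * resid))
    tol_sq = (1e-12 * rhs_norm) ** 2
    if rs < tol_sq:
        return s
    for _ in range(4 * r * r):
        hp = normal_op(p)
        denom = float(np.sum(p * hp))
        if denom <= 0.0:
            break  # (numerically) singular direction
        alpha = rs / denom
        s = s + alpha * p
        resid = resid - alpha * hp
        rs_new = float(np.sum(resid * resid))
        if rs_new < tol_sq:
            return s
        p = resid + (rs_new / rs) * p
        rs = rs_new
    if rs <= (1e-7 * rhs_norm) ** 2:
        # close enough for an ill-conditioned system: the remaining error
        # is far below the misfit scale the outer descent works at
        return s
    # CG made no real progress: the system is near singular; the dense
    # solver settles it and diagnoses rank deficiency
    return _solve_core_direct(left, right, block, block_index)


def cost(
    left: np.ndarray,
    right: np.ndarray,
    block: MaskedMatrix,
    core: np.ndarray | None = None,
) -> float:
    """Observed-entry misfit F(X, Y) = ||P_Omega(M - X S* Y^T)||_F with the
    optimal core (computed here unless supplied)."""
    if core is None:
        core = solve_core(left, right, block)
    resid = (block.values - left @ core @ right.T)[block.mask]
    return float(np.linalg.norm(resid))


def _qr_retract(a: np.ndarray) -> np.ndarray:
    """Orthonormalize columns via QR with a positive-diagonal convention."""
    q, r = np.linalg.qr(a)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


def complete(
    block: MaskedMatrix,
    rank: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    degree_factor: float = 2.0,
    row_penalty: float = 0.0,
    n_restarts: int = 0,
    restart_seed: int = 0,
) -> CompletionResult:
    """Complete a masked block with a rank-``rank`` model.

    Starting from the spectral initialization, performs projected steepest
    descent on the orthonormal pair (X, Y): the Euclidean gradient of the
    squared misfit is projected onto the horizontal space (I - XX^T)...,
    a backtracking line search with an Armijo condition picks the step, and
    QR retraction restores orthonormality.  The core is re-solved exactly
    after each accepted step, so the reported cost sequence is guaranteed
    nonincreasing.  Stops when the relative cost decrease falls below
    ``tol`` or at ``max_iter``.

    When the line search stalls at a non-negligible cost (a saddle of the
    factored objective — spectral initializations can land on symmetric
    configurations that plain descent cannot leave), the factors are
    perturbed with a small seeded jitter and descent resumes; an iterate is
    accepted, and recorded in ``cost_history``, only when it improves on
    the best cost seen, so the history stays nonincreasing and the returned
    factorization is always the best one found.  The fallback is
    deterministic through ``restart_seed``.

    Parameters
    ----------
    row_penalty : float
        Optional weight of a hinge barrier on factor row norms
        (incoherence control).  Zero (default) reproduces the plain
        observed-entry cost.
    n_restarts : int
        Maximum number of seeded perturbation restarts after a stall.
    restart_seed : int
        Seed of the perturbation stream (the solver is otherwise
        deterministic).

    Raises
    ------
    InfeasibleBlockError
        If any row or column has no observed entry.
    DataError
        If observed values are non-finite.
    """
    if not np.all(np.isfinite(block.values[block.mask])):
        raise DataError("observed entries contain non-finite values")
    miss_r, miss_c = block.missing_rows(), block.missing_cols()
    if miss_r or miss_c:
        raise InfeasibleBlockError(miss_r, miss_c)

    fact = svd_initialize(block, rank, degree_factor)
    x, y = fact.left, fact.right
    s = solve_core(x, y, block)
    current = cost(x, y, block, core=s)
    history = [current]
    # absolute floor: an (essentially) exact fit of the observed entries
    # counts as converged even if the relative decrease is still large
    floor = 1e-10 * max(1.0, float(np.linalg.norm(block.values[block.mask])))
    converged = False
    step = 1.0
    it = 0
    mask = block.mask
    vals = block.values

    c_dim, t_dim = block.shape
    # hinge barrier thresholds from the standard incoherence bound
    thr_x = 3.0 * rank / c_dim
    thr_y = 3.0 * rank / t_dim

    def penalty_and_grad(x, y):
        if row_penalty == 0.0:
            return 0.0, 0.0, 0.0
        zx = np.sum(x * x, axis=1) / thr_x - 1.0
        zy = np.sum(y * y, axis=1) / thr_y - 1.0
        hx = np.maximum(zx, 0.0)
        hy = np.maximum(zy, 0.0)
        pen = row_penalty * (np.sum(hx**2) + np.sum(hy**2))
        gx = row_penalty * (4.0 / thr_x) * hx[:, None] * x
        gy = row_penalty * (4.0 / thr_y) * hy[:, None] * y
        return pen, gx, gy

    best = (x, y, s)
    best_cost = current
    restart_rng = np.random.default_rng(restart_seed)
    restarts_left = n_restarts
    jitter = 0.02
    prev = None
    patience = 10  # consecutive sub-tol improvements before stopping
    slow_count = 0

    for it in range(1, max_iter + 1):
        model = x @ s @ y.T
        resid = np.where(mask, model - vals, 0.0)
        f_sq = float(np.sum(resid * resid))
        pen, pgx, pgy = penalty_and_grad(x, y)
        f_sq += pen
        gx = resid @ y @ s.T
        gy = resid.T @ x @ s
        if row_penalty != 0.0:
            gx = gx + pgx
            gy = gy + pgy
        # project onto the horizontal (tangent) space of the subspace pair
        gx = gx - x @ (x.T @ gx)
        gy = gy - y @ (y.T @ gy)
        gnorm_sq = float(np.sum(gx * gx) + np.sum(gy * gy))
        stalled = gnorm_sq <= 1e-30 * max(1.0, f_sq)
        if not stalled:
            # Barzilai-Borwein initial step (spectral step length): adapts
            # to the local curvature and rescues the slow zigzag of plain
            # steepest descent in ill-conditioned valleys; the Armijo
            # backtracking below keeps every accepted step cost-decreasing
            if prev is not None:
                dx = x - prev[0]
                dy = y - prev[1]
                dgx = gx - prev[2]
                dgy = gy - prev[3]
                sty = float(np.sum(dx * dgx) + np.sum(dy * dgy))
                sts = float(np.sum(dx * dx) + np.sum(dy * dy))
                if sty > 1e-300:
                    step = sts / sty
                else:
                    step = step * 2.0
            else:
                step = step * 2.0
            step = min(max(step, 1e-12), 1e6 / max(gnorm_sq, 1e-300))
            prev = (x, y, gx, gy)
            accepted = False
            for trial in range(50):
                xn = _qr_retract(x - step * gx)
                yn = _qr_retract(y - step * gy)
                # the first (Barzilai-Borwein) trial is judged with the
                # core re-solved exactly, so long valley-following steps
                # are not rejected because of a stale core; the cheaper
                # halved steps reuse the current core (any accepted
                # decrease only improves after the exact re-solve below)
                if trial == 0:
                    sn = solve_core(xn, yn, block, warm_start=s)
                else:
                    sn = None
                s_eval = sn if sn is not None else s
                resid_n = np.where(mask, xn @ s_eval @ yn.T - vals, 0.0)
                fit_sq = float(np.sum(resid_n * resid_n))
                f_new = fit_sq + penalty_and_grad(xn, yn)[0]
                if f_new <= f_sq - 1e-4 * step * gnorm_sq:
                    accepted = True
                    break
                step *= 0.5
            stalled = not accepted
        stop_candidate = stalled
        if not stalled:
            if sn is None:
                sn = solve_core(xn, yn, block, warm_start=s)
                fit_sq = float(
                    np.sum(np.where(mask, xn @ sn @ yn.T - vals, 0.0) ** 2)
                )
            x, y, s = xn, yn, sn
            new_cost = float(np.sqrt(fit_sq))
            if new_cost < best_cost:
                best = (x, y, s)
                # accepted improvement over the incumbent: record it
                history.append(new_cost)
                best_cost = new_cost
            # convergence of the current descent segment: the cost has to
            # stay flat for `patience` consecutive iterations (a single
            # small step after a large exact-line-search jump does not
            # mean the subspace has stopped turning)
            if current - new_cost <= tol * max(new_cost, 1e-300):
                slow_count += 1
            else:
                slow_count = 0
            stop_candidate = new_cost <= floor or slow_count >= patience
            current = new_cost
        if stop_candidate:
            if best_cost <= floor or restarts_left == 0:
                converged = True
                break
            # stationary point or flat basin that may be a saddle of the
            # factored objective: perturb the incumbent and keep descending
            restarts_left -= 1
            bx, by, bs = best
            x = _qr_retract(bx + jitter * restart_rng.normal(size=bx.shape))
            y = _qr_retract(by + jitter * restart_rng.normal(size=by.shape))
            s = solve_core(x, y, block, warm_start=bs)
            current = cost(x, y, block, core=s)
            jitter *= 5.0
            step = 1.0
            prev = None
            slow_count = 0

    x, y, s = best
    fact = Factorization(left=x, core=s, right=y)
    return CompletionResult(
        completed=fact.model(),
        factorization=fact,
        iterations=it,
        final_cost=best_cost,
        converged=converged,
        cost_history=np.asarray(history),
    )


class LowRankCompletion:
    """Model-style front end: a low-rank model of a masked block.

    Examples
    --------
    >>> res = LowRankCompletion(values, mask, rank=8).fit()
    >>> res.completed          # low-rank regeneration of the block
    >>> print(res.summary())
    """

    def __init__(self, values, mask, rank, degree_factor=2.0, row_penalty=0.0):
        self.block = MaskedMatrix(values, mask)
        self.rank = int(rank)
        self.degree_factor = degree_factor
        self.row_penalty = row_penalty

    def fit(self, max_iter: int = 200, tol: float = 1e-6) -> CompletionResult:
        return complete(
            self.block,
            self.rank,
            max_iter=max_iter,
            tol=tol,
            degree_factor=self.degree_factor,
            row_penalty=self.row_penalty,
        )
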