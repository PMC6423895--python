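"""Human-branch acceleration tests calibrated on local ancient repeats.

The procedure mirrors the classic accelerated-region framework: a neutral
substitution model (HKY85 + branch lengths) is fitted by maximum likelihood on
an ancient repeat element (ARE) assumed neutral, and the paired DNaseI
hypersensitive site (DHS) is scored with two one-sided likelihood-ratio tests
on the human terminal branch:

* **sub-branch test (A)** — the alternative scales only the human terminal
  branch by a factor rho >= 1;
* **sub-branch-given-tree test (B)** — a free factor nu > 0 rescales the
  whole DHS tree (absorbing element-wide rate differences), and the
  alternative adds the human-branch factor rho >= 1 on top.

The neutral human-branch length is itself an estimate from a short ARE, and
treating it as exact inflates the null variance of both statistics by
1 + n_DHS/n_ARE — enough to break FDR control at realistic element sizes.
When the neutral model carries its calibration alignment (the default when it
comes from :func:`fit_neutral_model`), both tests therefore profile the
shared human branch length in a JOINT likelihood over ARE + DHS: under the
null the two elements share one human branch length (times nu for the DHS in
test B), under the alternative the DHS human branch is additionally scaled by
rho >= 1. Without calibration data the neutral model is taken as known and
the tests reduce to the fixed-neutral form.

Because rho = 1 lies on the boundary of the alternative, the null distribution
of each LR statistic is the 50:50 mixture of a point mass at 0 and chi-square
with one degree of freedom; p = 1 when the fitted rho sticks to the boundary,
else 0.5 * P(chi2_1 >= LR).

Elements are declared accelerated when BOTH tests survive Benjamini-Hochberg
FDR control, with a strict-majority vote across sliding sub-ARE windows when
the ARE is long enough to be windowed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .alignment import OrthologAlignment
from .hky import HKYModel, PruningEngine, Tree

MIN_TESTABLE_COLUMNS = 50
_RHO_MAX = 100.0
_NU_BOUNDS = (1e-3, 100.0)
_BRANCH_MAX = 3.0
_FTOL = 1e-6


@dataclass
class NeutralModel:
    """Fixed topology + ML branch lengths + HKY parameters fitted on an ARE.

    ``calibration`` keeps the ARE alignment the model was fitted on, so the
    acceleration tests can profile the shared human branch instead of
    treating the fitted value as exact.
    """

    tree: Tree
    kappa: float
    pi: np.ndarray
    loglik: float
    converged: bool = True
    element_id: str | None = None
    calibration: OrthologAlignment | None = None

    def model(self) -> HKYModel:
        return HKYModel(self.kappa, self.pi)


@dataclass
class AccelerationResult:
    """Per-(DHS, window) outcome of the dual acceleration tests."""

    element_id: str
    window: int = 0
    n_windows: int = 1
    lnl_neutral: float = math.nan
    lnl_null_a: float = math.nan
    lnl_alt_a: float = math.nan
    rho_a: float = math.nan
    lr_a: float = math.nan
    p_a: float = math.nan
    lnl_null_b: float = math.nan
    lnl_alt_b: float = math.nan
    nu_b: float = math.nan
    rho_b: float = math.nan
    lr_b: float = math.nan
    p_b: float = math.nan
    q_a: float = math.nan
    q_b: float = math.nan
    untestable: bool = False
    accelerated: bool = False


def _prepare(aln: OrthologAlignment, tree: Tree):
    """Patterns + tree restricted to the alignment's species."""
    extra = set(aln.species) - tree.species
    if extra:
        raise KeyError(f"{aln.id}: species not in tree: {sorted(extra)}")
    sub = tree.pruned_to(set(aln.species)) if set(aln.species) != tree.species else tree
    pat, cnt, order = aln.patterns()
    return pat, cnt, order, sub


def observed_base_frequencies(aln: OrthologAlignment, floor: float = 1e-4) -> np.ndarray:
    """Base frequencies pooled over all species, floored away from zero."""
    counts = np.zeros(4)
    for codes in aln.codes().values():
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError(f"{aln.id}: alignment contains no bases (all gap/N)")
    pi = counts / counts.sum()
    pi = np.maximum(pi, floor)
    return pi / pi.sum()


def fit_neutral_model(
    are_aln: OrthologAlignment,
    topology: Tree,
    max_sweeps: int = 200,
    tol: float = _FTOL,
    init_kappa: float = 2.0,
) -> NeutralModel:
    """ML fit of the HKY neutral model on an ARE, topology fixed.

    Base frequencies are set to the observed frequencies; kappa and all branch
    lengths are maximised by bounded coordinate ascent until the log-likelihood
    improves by less than ``tol`` in a full sweep (or ``max_sweeps`` sweeps,
    in which case the model is flagged unconverged). The topology's branch
    lengths (if positive) and ``init_kappa`` seed the ascent, so a previous
    fit can warm-start a fit on overlapping data.
    """
    pi = observed_base_frequencies(are_aln)
    pat, cnt, order, tree = _prepare(are_aln, topology)
    tree = tree.copy()
    free = tree.free_branches()
    if not np.all(tree.blen[free] > 0):
        tree.blen[free] = np.maximum(tree.blen[free], 0.05)

    engine = PruningEngine(pat, cnt, order, tree)
    state = {"kappa": init_kappa, "model": HKYModel(init_kappa, pi)}

    def loglik() -> float:
        return engine.loglik(state["model"])

    def set_kappa(logk: float) -> float:
        k = math.exp(logk)
        if k != state["kappa"]:
            state["kappa"] = k
            state["model"] = HKYModel(k, pi)
        return -loglik()

    current = loglik()
    converged = False
    for _ in range(max_sweeps):
        res = optimize.minimize_scalar(
            set_kappa, bounds=(math.log(0.05), math.log(50.0)),
            method="bounded", options={"xatol": 1e-7},
        )
        set_kappa(res.x)
        for i in free:
            f = engine.branch_objective(state["model"], i)
            res = optimize.minimize_scalar(
                lambda t: -f(t), bounds=(0.0, _BRANCH_MAX),
                method="bounded", options={"xatol": 1e-8},
            )
            tree.blen[i] = res.x
        new = loglik()
        if new - current < tol:
            current = max(new, current)
            converged = True
            break
        current = new
    if not converged:
        warnings.warn(
            f"{are_aln.id}: neutral-model fit did not converge in {max_sweeps} sweeps",
            RuntimeWarning,
        )
    return NeutralModel(
        tree=tree, kappa=state["kappa"], pi=pi, loglik=current,
        converged=converged, element_id=are_aln.id, calibration=are_aln,
    )


def _boundary_mixture_p(lr: float, rho_hat: float) -> float:
    """One-sided p under the 0.5*delta_0 + 0.5*chi2_1 boundary null."""
    if lr <= 1e-9 or rho_hat <= 1.0 + 1e-9:
        return 1.0
    return max(0.5 * float(stats.chi2.sf(lr, df=1)), np.nextafter(0, 1))


def _argmax_scalar(f, lo: float, hi: float, xatol: float = 1e-7):
    res = optimize.minimize_scalar(
        lambda x: -f(x), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), float(-res.fun)


def _argmax_log_scalar(f, lo: float, hi: float, xatol: float = 1e-6):
    res = optimize.minimize_scalar(
        lambda x: -f(math.exp(x)), bounds=(math.log(lo), math.log(hi)),
        method="bounded", options={"xatol": xatol},
    )
    return float(math.exp(res.x)), float(-res.fun)


def acceleration_test(
    dhs_aln: OrthologAlignment, neutral: NeutralModel
) -> AccelerationResult:
    """Dual one-sided LR tests for human-branch acceleration of one DHS.

    If the neutral model carries its calibration ARE, the shared human branch
    is profiled in the joint ARE+DHS likelihood (see module docstring);
    otherwise the neutral model is treated as exact. Returns unadjusted
    p-values; q-values and final calls are assigned by
    :func:`call_accelerated` over the full collection of tests.
    """
    if "human" not in dhs_aln.species:
        raise KeyError(f"{dhs_aln.id}: human sequence required")
    result = AccelerationResult(element_id=dhs_aln.id)
    if dhs_aln.n_informative_columns() < MIN_TESTABLE_COLUMNS:
        result.untestable = True
        return result

    species = [s for s in dhs_aln.species if s in neutral.tree.species]
    aln = dhs_aln.subset(species) if len(species) != len(dhs_aln.species) else dhs_aln
    pat, cnt, order, tree = _prepare(aln, neutral.tree)
    model = neutral.model()
    human = tree.terminal_branch("human")
    t_h = float(tree.blen[human])
    eng_d = PruningEngine(pat, cnt, order, tree)
    result.lnl_neutral = eng_d.loglik(model)

    cal = neutral.calibration
    f_r = None
    if cal is not None and "human" in cal.species:
        pat_r, cnt_r, order_r, tree_r = _prepare(cal, neutral.tree)
        eng_r = PruningEngine(pat_r, cnt_r, order_r, tree_r)
        f_r = eng_r.branch_objective(model, tree_r.terminal_branch("human"))

    if f_r is not None:
        lnl_a0, lnl_a1, rho_a = _profiled_test_a(eng_d, f_r, model, human)
        lnl_b0, lnl_b1, nu, rho_b = _profiled_test_b(eng_d, f_r, model, human)
    else:
        lnl_a0, lnl_a1, rho_a = _fixed_test_a(
            eng_d, model, human, t_h, result.lnl_neutral
        )
        lnl_b0, lnl_b1, nu, rho_b = _fixed_test_b(
            eng_d, model, human, t_h, result.lnl_neutral
        )

    lr_a = max(0.0, 2.0 * (lnl_a1 - lnl_a0))
    lr_b = max(0.0, 2.0 * (lnl_b1 - lnl_b0))
    result.lnl_null_a = lnl_a0
    result.lnl_alt_a, result.rho_a, result.lr_a = lnl_a1, rho_a, lr_a
    result.p_a = _boundary_mixture_p(lr_a, rho_a)
    result.lnl_null_b, result.lnl_alt_b = lnl_b0, lnl_b1
    result.nu_b, result.rho_b, result.lr_b = nu, rho_b, lr_b
    result.p_b = _boundary_mixture_p(lr_b, rho_b)
    return result


def _profiled_test_a(eng_d, f_r, model, human):
    """Joint ARE+DHS sub-branch test: shared human branch under the null,
    DHS human branch scaled by rho >= 1 under the alternative."""
    f_d = eng_d.branch_objective(model, human)
    x_r, v_r = _argmax_scalar(f_r, 0.0, _BRANCH_MAX)
    x_d, v_d = _argmax_scalar(f_d, 0.0, _BRANCH_MAX)
    _, null = _argmax_scalar(lambda x: f_r(x) + f_d(x), 0.0, _BRANCH_MAX)
    rho = x_d / max(x_r, 1e-9)
    if rho <= 1.0 or v_r + v_d <= null:
        return null, null, 1.0
    if rho > _RHO_MAX:
        rho = _RHO_MAX
        _, alt = _argmax_scalar(
            lambda x: f_r(x) + f_d(_RHO_MAX * x), 0.0, _BRANCH_MAX / _RHO_MAX
        )
        alt = max(alt, null)
    else:
        alt = v_r + v_d
    return null, alt, rho


def _profiled_test_b(eng_d, f_r, model, human):
    """Joint sub-branch-given-tree test: a free DHS tree scale nu in both
    hypotheses, shared human branch profiled, rho >= 1 in the alternative."""
    x_r, v_r = _argmax_scalar(f_r, 0.0, _BRANCH_MAX)

    def null_given_nu(nu: float):
        f_d = eng_d.branch_objective(model, human, tree_scale=nu)
        return _argmax_scalar(
            lambda x: f_r(x) + f_d(nu * x), 0.0, _BRANCH_MAX
        )

    nu0, lnl_b0 = 1.0, -math.inf
    x_shared = 0.0
    for _ in range(40):
        x_shared, v = null_given_nu(nu0)
        nu_new, v2 = _argmax_log_scalar(
            lambda n: f_r(x_shared)
            + eng_d.loglik(model, tree_scale=n, branch_override={human: n * x_shared}),
            *_NU_BOUNDS,
        )
        nu0 = nu_new
        if v2 - lnl_b0 < 1e-8:
            lnl_b0 = max(v2, lnl_b0)
            break
        lnl_b0 = v2

    # alternative: ARE human branch decouples (x = x_r), DHS human free >= nu*x_r
    nu, rho = nu0, 1.0
    lnl_b1 = lnl_b0
    for _ in range(40):
        f_d = eng_d.branch_objective(model, human, tree_scale=nu)
        h, _ = _argmax_scalar(f_d, 0.0, _BRANCH_MAX)
        rho = min(max(h / max(nu * x_r, 1e-9), 1.0), _RHO_MAX)
        nu_new, v = _argmax_log_scalar(
            lambda n: v_r
            + eng_d.loglik(model, tree_scale=n, branch_override={human: n * x_r * rho}),
            *_NU_BOUNDS,
        )
        nu = nu_new
        if v - lnl_b1 < 1e-8:
            lnl_b1 = max(v, lnl_b1)
            break
        lnl_b1 = v
    if lnl_b1 <= lnl_b0:
        return lnl_b0, lnl_b0, nu0, 1.0
    return lnl_b0, lnl_b1, nu, rho


def _fixed_test_a(eng_d, model, human, t_h, lnl0):
    """Fixed-neutral sub-branch test (neutral model treated as exact)."""
    f_a = eng_d.branch_objective(model, human)
    rho, lnl_a = _argmax_log_scalar(
        lambda r: f_a(t_h * r), 1.0, _RHO_MAX
    )
    if lnl0 >= lnl_a:
        return lnl0, lnl0, 1.0
    return lnl0, lnl_a, rho


def _fixed_test_b(eng_d, model, human, t_h, lnl0):
    """Fixed-neutral sub-branch-given-tree test."""
    nu0, lnl_b0 = _argmax_log_scalar(
        lambda n: eng_d.loglik(model, tree_scale=n), *_NU_BOUNDS
    )
    lnl_b0 = max(lnl_b0, lnl0)
    nu, rho = nu0, 1.0
    lnl_b1 = lnl_b0
    for _ in range(60):
        f_b = eng_d.branch_objective(model, human, tree_scale=nu)
        rho, _ = _argmax_log_scalar(
            lambda r: f_b(t_h * nu * r), 1.0, _RHO_MAX
        )
        nu, v = _argmax_log_scalar(
            lambda n: eng_d.loglik(model, {human: rho}, tree_scale=n),
            *_NU_BOUNDS,
        )
        if v - lnl_b1 < 1e-8:
            lnl_b1 = max(v, lnl_b1)
            break
        lnl_b1 = v
    if lnl_b1 <= lnl_b0:
        return lnl_b0, lnl_b0, nu0, 1.0
    return lnl_b0, lnl_b1, nu, rho


def sliding_sub_ares(
    are_aln: OrthologAlignment, dhs_length: int
) -> list[OrthologAlignment]:
    """Sub-ARE windows matched to the DHS length.

    If the human ARE is at most twice the DHS length the whole ARE is the
    single window. Otherwise windows of human-coordinate width W = dhs_length
    slide with step 10% of W (full windows only), and each window is sliced
    from the alignment by human non-gap positions.
    """
    if dhs_length < 100:
        raise ValueError("window width below the 100 bp element minimum")
    human_len = len(are_aln.ungapped("human"))
    if human_len <= 2 * dhs_length:
        return [are_aln]
    w = dhs_length
    step = max(1, round(0.1 * w))
    cols = are_aln.column_of_position("human")
    out = []
    for k, off in enumerate(range(0, human_len - w + 1, step)):
        start, stop = cols[off], cols[off + w - 1] + 1
        out.append(are_aln.slice_columns(start, stop, f"{are_aln.id}.w{k}"))
    return out


def test_element(
    dhs_aln: OrthologAlignment,
    are_aln: OrthologAlignment,
    topology: Tree,
) -> list[AccelerationResult]:
    """Full per-element procedure: window the ARE, fit, test the DHS.

    Each sub-ARE window yields its own neutral fit (warm-started from the
    previous, heavily overlapping window) and the DHS is tested against each.
    Unconverged window fits are dropped with a warning already emitted by the
    fitter.
    """
    dhs_len = len(dhs_aln.ungapped("human"))
    windows = sliding_sub_ares(are_aln, dhs_len)
    results: list[AccelerationResult] = []
    prev: NeutralModel | None = None
    for w_idx, sub in enumerate(windows):
        top = prev.tree if prev is not None else topology
        neutral = fit_neutral_model(
            sub, top, init_kappa=prev.kappa if prev else 2.0
        )
        if not neutral.converged:
            continue
        prev = neutral
        res = acceleration_test(dhs_aln, neutral)
        res.window, res.n_windows = w_idx, len(windows)
        results.append(res)
    return results


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ecdf = np.arange(1, m + 1) / m
    ranked = p[order] / ecdf
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class AccelerationCalls:
    """Final per-element calls after FDR control and window voting."""

    results: list[AccelerationResult]
    accelerated_ids: list[str] = field(default_factory=list)
    votes: dict[str, tuple[int, int]] = field(default_factory=dict)


def call_accelerated(
    results: list[AccelerationResult], alpha: float = 0.05
) -> AccelerationCalls:
    """BH-FDR both test families, then strict-majority voting over windows.

    q_A and q_B are each computed over the full collection of testable
    (DHS, window) pairs. A window is significant iff both q-values fall below
    ``alpha``; a DHS is accelerated iff its significant windows outnumber half
    of its total windows (strict), which for a single window reduces to that
    window being significant.
    """
    testable = [r for r in results if not r.untestable]
    if testable:
        qa = bh_fdr([r.p_a for r in testable])
        qb = bh_fdr([r.p_b for r in testable])
        for r, a, b in zip(testable, qa, qb):
            r.q_a, r.q_b = float(a), float(b)
    votes: dict[str, list[int]] = {}
    for r in results:
        sig = (not r.untestable) and r.q_a < alpha and r.q_b < alpha
        tally = votes.setdefault(r.element_id, [0, 0])
        tally[0] += int(sig)
        tally[1] += 1
    accelerated = sorted(eid for eid, (s, t) in votes.items() if s > t / 2)
    accel_set = set(accelerated)
    for r in results:
        r.accelerated = r.element_id in accel_set
    return AccelerationCalls(
        results=results,
        accelerated_ids=accelerated,
        votes={k: (v[0], v[1]) for k, v in votes.items()},
    )
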