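"""Operating-characteristic experiments for the acceleration machinery.

These are the simulation studies a user runs to convince themselves the
statistics behave: neutral-model parameter recovery, type-I calibration of
the dual tests, power and planted-element recovery at the fixture's study
conditions, and the power curve over acceleration factors. They are used by
the test suite and by ``scripts/acceptance.py``.

All experiments are deterministic given their seed; seeds derived internally
stay below 2**31.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import phylo
from .hky import Tree
from .simulate import (
    DEFAULT_ARE_LENGTH,
    DEFAULT_DHS_LENGTH,
    DEFAULT_TREE,
    SimulationConfig,
    simulate_alignment,
)

#: Deep-branch tree for parameter-recovery experiments. The relative error of
#: a branch-length MLE scales as 1/sqrt(n*t) and is further inflated by
#: correlation between adjacent branch estimates, so the recovery experiment
#: uses a compact 4-taxon tree with uniform 0.1-substitution branches: at
#: 10 kb each estimate has ~3.5-4% standard error, leaving clear margin for
#: the worst of ~120 draws under a 15% bound.
RECOVERY_TREE = "((human:0.10,chimp:0.10):0.10,gorilla:0.10,macaque:0.10);"


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


@dataclass
class RecoveryReport:
    max_branch_rel_error: float
    max_kappa_rel_error: float
    n_replicates: int
    branch_errors: list[float] = field(default_factory=list)


def neutral_recovery(
    n_replicates: int = 20,
    length: int = 10_000,
    kappa: float = 4.0,
    topology: str = RECOVERY_TREE,
    seed: int = 0,
) -> RecoveryReport:
    """Fit the neutral model on simulated AREs of known parameters.

    Reports the worst relative error of any branch length and of kappa over
    the replicates.
    """
    rng = np.random.default_rng(seed)
    true_tree = Tree.from_newick(topology)
    branch_errors: list[float] = []
    kappa_errors: list[float] = []
    for _ in range(n_replicates):
        cfg = SimulationConfig(
            topology=topology, kappa=kappa, element_length=length,
            seed=_child_seed(rng),
        )
        aln = simulate_alignment(cfg, "are")
        nm = phylo.fit_neutral_model(aln, true_tree)
        for node in true_tree.free_branches():
            t_true = float(true_tree.blen[node])
            t_hat = float(nm.tree.blen[node])
            branch_errors.append(abs(t_hat - t_true) / t_true)
        kappa_errors.append(abs(nm.kappa - kappa) / kappa)
    return RecoveryReport(
        max_branch_rel_error=max(branch_errors),
        max_kappa_rel_error=max(kappa_errors),
        n_replicates=n_replicates,
        branch_errors=branch_errors,
    )


@dataclass
class CalibrationReport:
    p_a_rate: float
    p_b_rate: float
    n_accelerated_calls: int
    n: int


def type1_calibration(
    n: int = 1000,
    dhs_length: int = 500,
    are_length: int = 10_000,
    topology: str = DEFAULT_TREE,
    seed: int = 0,
) -> CalibrationReport:
    """Null rejection rates of the dual tests on neutral DHS simulations.

    One neutral model is fitted on a long simulated ARE; ``n`` neutral DHSs
    are then tested against it. Reports empirical P(p < 0.05) per test and
    the number of elements called accelerated after BH-FDR at 0.05.
    """
    rng = np.random.default_rng(seed)
    tree = Tree.from_newick(topology)
    are = simulate_alignment(
        SimulationConfig(topology=topology, element_length=are_length,
                         seed=_child_seed(rng)),
        "calibration_are",
    )
    neutral = phylo.fit_neutral_model(are, tree)
    results = []
    for k in range(n):
        dhs = simulate_alignment(
            SimulationConfig(topology=topology, element_length=dhs_length,
                             seed=_child_seed(rng)),
            f"null{k:04d}",
        )
        results.append(phylo.acceleration_test(dhs, neutral))
    p_a = np.array([r.p_a for r in results])
    p_b = np.array([r.p_b for r in results])
    calls = phylo.call_accelerated(results, alpha=0.05)
    return CalibrationReport(
        p_a_rate=float(np.mean(p_a < 0.05)),
        p_b_rate=float(np.mean(p_b < 0.05)),
        n_accelerated_calls=len(calls.accelerated_ids),
        n=n,
    )


@dataclass
class PowerReport:
    recall: float
    fdp: float
    n_elements: int
    n_accelerated: int
    n_called: int


def power_recovery(
    n_elements: int = 500,
    n_accelerated: int = 50,
    rho: float = 3.0,
    dhs_length: int = DEFAULT_DHS_LENGTH,
    are_length: int = DEFAULT_ARE_LENGTH,
    topology: str = DEFAULT_TREE,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerReport:
    """Planted-element recovery at the fixture's study conditions.

    Each element gets its own simulated ARE (windowed when longer than twice
    the DHS) and DHS; the full per-element procedure runs, BH-FDR and the
    window majority vote are applied, and recall / false-discovery proportion
    against the planted truth are reported.
    """
    rng = np.random.default_rng(seed)
    tree = Tree.from_newick(topology)
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for k in range(n_elements):
            r = rho if k < n_accelerated else 1.0
            are = simulate_alignment(
                SimulationConfig(topology=topology, element_length=are_length,
                                 seed=_child_seed(rng)),
                f"e{k:04d}_are",
            )
            dhs = simulate_alignment(
                SimulationConfig(topology=topology, element_length=dhs_length,
                                 human_rate_multiplier=r, seed=_child_seed(rng)),
                f"e{k:04d}",
            )
            results += phylo.test_element(dhs, are, tree)
    calls = phylo.call_accelerated(results, alpha=alpha)
    called = set(calls.accelerated_ids)
    tp = sum(1 for k in range(n_accelerated) if f"e{k:04d}" in called)
    fp = len(called) - tp
    return PowerReport(
        recall=tp / n_accelerated,
        fdp=fp / max(1, len(called)),
        n_elements=n_elements,
        n_accelerated=n_accelerated,
        n_called=len(called),
    )


def power_curve(
    rhos: tuple = (1.5, 2.0, 3.0, 5.0),
    n_per_rho: int = 150,
    dhs_length: int = DEFAULT_DHS_LENGTH,
    are_length: int = 10_000,
    topology: str = DEFAULT_TREE,
    seed: int = 0,
) -> dict[float, float]:
    """Per-test power P(p_A < 0.05) as a function of the rate multiplier.

    A single well-calibrated neutral model (long ARE) is shared, isolating
    the test's power from calibration noise.
    """
    rng = np.random.default_rng(seed)
    tree = Tree.from_newick(topology)
    are = simulate_alignment(
        SimulationConfig(topology=topology, element_length=are_length,
                         seed=_child_seed(rng)),
        "power_are",
    )
    neutral = phylo.fit_neutral_model(are, tree)
    curve: dict[float, float] = {}
    for rho in rhos:
        hits = 0
        for k in range(n_per_rho):
            dhs = simulate_alignment(
                SimulationConfig(topology=topology, element_length=dhs_length,
                                 human_rate_multiplier=rho,
                                 seed=_child_seed(rng)),
                f"p{rho}_{k}",
            )
            res = phylo.acceleration_test(dhs, neutral)
            hits += res.p_a < 0.05
        curve[rho] = hits / n_per_rho
    return curve
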