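"""Structured-coalescent simulation of unlinked biallelic SNP loci.

The generative model is the continuous-time coalescent in a set of demes of
constant diploid size N: while a deme holds k lineages, the waiting time to
its next coalescence is exponential with rate k(k-1)/2 x 1/(2N) per
generation.  Backward in time, merge events pour the lineages of two demes
into their ancestral deme, and admixture events route each lineage of the
hybrid deme to one of its two parents independently (probability ``r1`` for
the PAM side).  After the final merge, coalescence proceeds in the single
ancestral deme until one lineage remains.

Each SNP is an independent tree on which a single mutation is placed on a
branch chosen with probability proportional to its length (the standard
fixed-segregating-sites device), so every simulated locus is polymorphic in
the sample; loci can additionally be conditioned on a pooled minor-allele
frequency by rejection, mirroring the ascertainment of the analyzed panel.
Diploid dosages pair the two gene copies of each individual; there is no
missing data, no recombination, and no selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .genotypes import SnpDataset
from .scenarios import DemographicScenario

__all__ = [
    "SampleConfig",
    "GeneTree",
    "SimulationCapError",
    "simulate_tree",
    "simulate_tree_ensemble",
    "drop_single_mutation",
    "simulate_snp_dataset",
]


class SimulationCapError(RuntimeError):
    """The per-locus rejection cap was exhausted.

    Signals a parameter draw under which polymorphic loci at the requested
    minor-allele frequency are vanishingly rare.
    """


@dataclass(frozen=True)
class SampleConfig:
    """Number of diploid individuals sampled per deme at time 0."""

    sizes: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sizes.values()):
            raise ValueError("sample sizes must be non-negative")
        if self.n_copies < 2:
            raise ValueError("at least two gene copies must be sampled")

    @property
    def n_individuals(self) -> int:
        return sum(self.sizes.values())

    @property
    def n_copies(self) -> int:
        return 2 * self.n_individuals

    def demes_sampled(self) -> list[str]:
        return [d for d, n in self.sizes.items() if n > 0]


@dataclass(frozen=True)
class GeneTree:
    """One coalescent realization, as flat parent/child/time arrays.

    Leaves are nodes ``0 .. n_leaves-1`` at time 0 (two consecutive leaves
    per diploid individual, in sample-configuration order); internal nodes
    carry coalescence times in generations; the root is the last node.
    """

    parent: np.ndarray
    node_time: np.ndarray
    left_child: np.ndarray
    right_child: np.ndarray
    n_leaves: int
    leaf_labels: tuple[tuple[str, int], ...] = field(repr=False)  # (individual_id, copy)

    @property
    def root(self) -> int:
        return self.parent.size - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    @property
    def total_branch_length(self) -> float:
        v = np.arange(self.parent.size - 1)
        return float((self.node_time[self.parent[v]] - self.node_time[v]).sum())

    def branch_lengths(self) -> np.ndarray:
        """Branch length above every node except the root."""
        v = np.arange(self.parent.size - 1)
        return self.node_time[self.parent[v]] - self.node_time[v]

    def leaves_below(self, node: int) -> np.ndarray:
        """Leaf ids in the clade subtended by ``node``."""
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.append(int(self.left_child[v]))
                stack.append(int(self.right_child[v]))
        return np.sort(np.asarray(out, dtype=int))

    def to_newick(self) -> str:
        """Newick string with leaf labels ``<individual>|<copy>`` (debug export)."""

        def fmt(v: int) -> str:
            if v < self.n_leaves:
                ind, copy = self.leaf_labels[v]
                return f"{ind}|{copy}"
            lb = fmt(int(self.left_child[v]))
            rb = fmt(int(self.right_child[v]))
            bl_l = self.node_time[v] - self.node_time[self.left_child[v]]
            bl_r = self.node_time[v] - self.node_time[self.right_child[v]]
            return f"({lb}:{bl_l:.6g},{rb}:{bl_r:.6g})"

        return fmt(self.root) + ";"


@dataclass(frozen=True)
class CompiledScenario:
    """Integer-coded scenario ready for the simulation kernels."""

    deme_names: tuple[str, ...]
    N: np.ndarray
    leaf_deme: np.ndarray  # per gene copy
    ev_time: np.ndarray
    ev_kind: np.ndarray
    ev_a: np.ndarray
    ev_b: np.ndarray
    ev_dest: np.ndarray
    ev_frac: np.ndarray
    individual_ids: tuple[str, ...]
    group_labels: tuple[str, ...]


def compile_scenario(scenario: DemographicScenario, config: SampleConfig) -> CompiledScenario:
    """Flatten a scenario and sample configuration into kernel arrays.

    Individuals are ordered by the sample configuration's deme order and
    named ``<deme>_<k>``; each contributes two consecutive gene copies.
    """
    for d in config.demes_sampled():
        if d not in scenario.leaf_demes:
            raise ValueError(f"sampled deme {d!r} is not a leaf deme of the scenario")
    names = tuple(scenario.sizes.keys())
    index = {d: i for i, d in enumerate(names)}
    N = np.array([float(scenario.sizes[d]) for d in names])
    if (N <= 0).any():
        raise ValueError("all effective sizes must be positive")

    leaf_deme = []
    individual_ids = []
    group_labels = []
    for d, n in config.sizes.items():
        for k in range(n):
            individual_ids.append(f"{d}_{k:03d}")
            group_labels.append(d)
            leaf_deme.extend([index[d], index[d]])
    leaf_deme = np.asarray(leaf_deme, dtype=np.int64)

    ev_time, ev_kind, ev_a, ev_b, ev_dest, ev_frac = [], [], [], [], [], []
    for e in scenario.events:
        ev_time.append(float(e.time))
        if e.kind == "merge":
            if len(e.children) != 2:
                raise ValueError("merge events must name exactly two child demes")
            ev_kind.append(0)
            ev_a.append(index[e.children[0]])
            ev_b.append(index[e.children[1]])
            ev_dest.append(index[e.dest])
            ev_frac.append(0.0)
        else:
            ev_kind.append(1)
            ev_a.append(index[e.child])
            ev_b.append(index[e.parent_a])
            ev_dest.append(index[e.parent_b])
            ev_frac.append(float(e.fraction_a))
    return CompiledScenario(
        names, N, leaf_deme,
        np.asarray(ev_time), np.asarray(ev_kind, np.int32),
        np.asarray(ev_a, np.int32), np.asarray(ev_b, np.int32),
        np.asarray(ev_dest, np.int32), np.asarray(ev_frac),
        tuple(individual_ids), tuple(group_labels),
    )


def _kernel_seed(rng: np.random.Generator) -> int:
    # numba's legacy np.random.seed accepts uint32
    return int(rng.integers(0, 2**32 - 1))


def _as_rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def simulate_tree(
    scenario: DemographicScenario, config: SampleConfig, rng
) -> GeneTree:
    """Simulate one gene tree for the sampled copies under the scenario.

    ``rng`` is a :class:`numpy.random.Generator` or a seed.
    """
    rng = _as_rng(rng)
    comp = compile_scenario(scenario, config)
    parent, ntime, lch, rch = _kernels.sim_tree_seeded(
        _kernel_seed(rng), comp.leaf_deme, comp.N,
        comp.ev_time, comp.ev_kind, comp.ev_a, comp.ev_b, comp.ev_dest, comp.ev_frac,
    )
    labels = tuple((ind, c) for ind in comp.individual_ids for c in (0, 1))
    return GeneTree(parent, ntime, lch, rch, comp.leaf_deme.size, labels)


def simulate_tree_ensemble(
    scenario: DemographicScenario, config: SampleConfig, n_reps: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Distributions of TMRCA and total branch length over independent trees.

    Returns two arrays of length ``n_reps`` (generations).  Batched in the
    simulation kernel, so large Monte Carlo checks stay cheap.
    """
    rng = _as_rng(rng)
    comp = compile_scenario(scenario, config)
    return _kernels.sim_tree_ensemble(
        _kernel_seed(rng), int(n_reps), comp.leaf_deme, comp.N,
        comp.ev_time, comp.ev_kind, comp.ev_a, comp.ev_b, comp.ev_dest, comp.ev_frac,
    )


def drop_single_mutation(tree: GeneTree, rng) -> np.ndarray:
    """Place one mutation on a branch chosen proportionally to its length.

    Returns a boolean derived-allele indicator over leaf copies.  Every
    branch subtends a proper subset of the leaves, so the resulting locus is
    always polymorphic in the sample.
    """
    rng = _as_rng(rng)
    carrier = _kernels.drop_mutation_seeded(
        _kernel_seed(rng), tree.parent, tree.node_time,
        tree.left_child, tree.right_child, tree.n_leaves,
    )
    return carrier.astype(bool)


def simulate_snp_dataset(
    scenario: DemographicScenario,
    config: SampleConfig,
    n_loci: int,
    min_maf: float,
    rng,
    max_attempts: int = 10_000,
    snp_model: str = "per_tree",
) -> SnpDataset:
    """Simulate a dataset of independent MAF-conditioned SNPs.

    Every locus is a fresh tree plus a single branch-proportional mutation,
    accepted only when the pooled minor-allele frequency is at least
    ``min_maf`` (rejection, at most ``max_attempts`` tries per locus).
    Raises :class:`SimulationCapError` when a locus exhausts the cap.

    ``snp_model`` selects how the single segregating site arises:

    ``"per_tree"`` (default)
        every simulated tree receives exactly one mutation.  This is the
        fixed-segregating-sites device used by coalescent SNP simulators;
        it slightly over-represents singletons relative to the classical
        neutral spectrum because short trees are as likely as long ones to
        carry the mutation.
    ``"length_biased"``
        trees are first accepted with probability proportional to their
        total branch length (rejection against a far-tail length cap
        calibrated from a pilot run), the low-mutation-rate limit of
        infinite-sites mutation conditioned on one segregating site.  The
        derived-allele spectrum then follows the neutral 1/i law.  Slower
        by roughly the inverse acceptance rate.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be at least 1")
    if not 0 <= min_maf < 0.5:
        raise ValueError("min_maf must lie in [0, 0.5)")
    if snp_model not in ("per_tree", "length_biased"):
        raise ValueError("snp_model must be 'per_tree' or 'length_biased'")
    rng = _as_rng(rng)
    comp = compile_scenario(scenario, config)
    lcap = 0.0
    if snp_model == "length_biased":
        # Far-tail cap: pilot mean plus 40 pair-coalescence scales of the
        # largest deme; P(L > cap) < 1e-15, so the truncation is negligible
        # while keeping the acceptance rate at a usable E[L]/cap.
        _, pilot = _kernels.sim_tree_ensemble(
            _kernel_seed(rng), 200, comp.leaf_deme, comp.N,
            comp.ev_time, comp.ev_kind, comp.ev_a, comp.ev_b, comp.ev_dest, comp.ev_frac,
        )
        lcap = float(pilot.mean() + 40.0 * 4.0 * comp.N.max())
    dosages, _rejects, failed = _kernels.sim_dataset(
        _kernel_seed(rng), config.n_individuals, int(n_loci), float(min_maf),
        int(max_attempts), lcap, comp.leaf_deme, comp.N,
        comp.ev_time, comp.ev_kind, comp.ev_a, comp.ev_b, comp.ev_dest, comp.ev_frac,
    )
    if failed >= 0:
        raise SimulationCapError(
            f"locus {failed}: no polymorphic locus with pooled MAF >= {min_maf} in "
            f"{max_attempts} attempts under scenario {scenario.scenario_id} "
            f"(sizes {scenario.sizes})"
        )
    individuals = pd.DataFrame(
        {"individual_id": comp.individual_ids, "group_label": comp.group_labels}
    )
    loci = pd.DataFrame(
        {
            "locus_id": [f"sim{j:06d}" for j in range(n_loci)],
            "clone_id": [f"clone{j:06d}" for j in range(n_loci)],
            "reproducibility": 1.0,
            "allele_ref": "A",
            "allele_alt": "T",
        }
    )
    return SnpDataset(individuals, loci, dosages)
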