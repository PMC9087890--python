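"""Structured-coalescent simulation for two demes with epochal migration.

Two code paths share one model description:

* :func:`accumulate_expected_jsfs` — a numba-compiled batch simulator that
  accumulates branch length per (west, east) descendant-count class over many
  genealogies (a Rao-Blackwellized estimate of the expected joint SFS shape,
  lower-variance than dropping Poisson mutations).
* :func:`simulate_genealogy` — a plain-Python single-genealogy simulator that
  keeps full topology (for newick export and for per-locus genotype
  simulation in the synthetic-data module).

Waiting times come from competing exponential clocks (continuous-time
approximation of the discrete-generation model, error O(1/N)); epoch
boundaries and the merge at T_div act as deterministic barriers at which the
state advances and clocks are redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import DemographicModel, ModelParameterError


class SampleConfigError(ValueError):
    """Raised for sample configurations that cannot coalesce."""


@dataclass(frozen=True)
class SampleConfig:
    """Haploid sample sizes per deme."""

    n_west: int
    n_east: int

    def __post_init__(self) -> None:
        if self.n_west < 0 or self.n_east < 0 or self.n_west + self.n_east < 2:
            raise SampleConfigError(
                "need nonnegative sample sizes with at least 2 samples in total"
            )


@dataclass
class BranchClassTotals:
    """Accumulated branch length per (i, j) descendant-count class.

    ``totals[i, j]`` is the summed length (generations) of branches with i
    sampled descendants in the west and j in the east, over ``n_genealogies``
    independent genealogies.  The (0, 0) and (n_west, n_east) classes are
    structurally zero (the latter is the root branch, which is excluded).
    ``tree_lengths`` holds the per-genealogy total tree length.
    """

    totals: np.ndarray
    n_genealogies: int
    tree_lengths: np.ndarray

    @property
    def mean_tree_length(self) -> float:
        return float(self.tree_lengths.mean())

    def normalized(self) -> np.ndarray:
        """Class masses normalized to sum to one over all classes."""
        s = self.totals.sum()
        return self.totals / s


@njit(cache=True)
def _simulate_batch(n_w, n_e, epoch_starts, size_w, size_e, mig_we, mig_ew,
                    t_div, n_anc, n_sims, seed):  # pragma: no cover - numba
    """Accumulate branch-class totals over n_sims genealogies.

    mig_we: backward rate, lineage in west jumps to east (per epoch).
    mig_ew: backward rate, lineage in east jumps to west (per epoch).
    """
    np.random.seed(seed)
    n = n_w + n_e
    totals = np.zeros((n_w + 1, n_e + 1))
    tree_lengths = np.empty(n_sims)
    n_epochs = len(epoch_starts)

    deme = np.empty(n, dtype=np.int8)
    wd = np.empty(n, dtype=np.int32)
    ed = np.empty(n, dtype=np.int32)

    for s in range(n_sims):
        for i in range(n_w):
            deme[i] = 0
            wd[i] = 1
            ed[i] = 0
        for i in range(n_e):
            deme[n_w + i] = 1
            wd[n_w + i] = 0
            ed[n_w + i] = 1
        k = n
        k0 = n_w
        k1 = n_e
        t = 0.0
        epoch = 0
        merged = False
        tot_len = 0.0

        while k > 1:
            if merged:
                nw_size = n_anc
                ne_size = n_anc  # unused: k1 == 0 after merge
                m0 = 0.0
                m1 = 0.0
                barrier = np.inf
            else:
                nw_size = size_w[epoch]
                ne_size = size_e[epoch]
                m0 = mig_we[epoch]
                m1 = mig_ew[epoch]
                if epoch + 1 < n_epochs:
                    barrier = epoch_starts[epoch + 1]
                else:
                    barrier = t_div

            rate_c0 = k0 * (k0 - 1) / (4.0 * nw_size)
            rate_c1 = k1 * (k1 - 1) / (4.0 * ne_size)
            rate_m0 = k0 * m0
            rate_m1 = k1 * m1
            total_rate = rate_c0 + rate_c1 + rate_m0 + rate_m1

            if total_rate > 0.0:
                dt = np.random.exponential(1.0 / total_rate)
            else:
                dt = np.inf

            if t + dt >= barrier:
                # advance to the barrier, accrue lengths, redraw clocks
                span = barrier - t
                for i in range(k):
                    totals[wd[i], ed[i]] += span
                tot_len += k * span
                t = barrier
                if not merged and epoch + 1 < n_epochs:
                    epoch += 1
                else:
                    # merge: all lineages into the ancestral deme (index 0)
                    merged = True
                    for i in range(k):
                        deme[i] = 0
                    k0 = k
                    k1 = 0
                continue

            for i in range(k):
                totals[wd[i], ed[i]] += dt
            tot_len += k * dt
            t += dt

            u = np.random.random() * total_rate
            if u < rate_c0 or u >= rate_c0 + rate_c1 + rate_m0 + rate_m1:
                target_deme = 0
                coalesce = True
            elif u < rate_c0 + rate_c1:
                target_deme = 1
                coalesce = True
            elif u < rate_c0 + rate_c1 + rate_m0:
                target_deme = 0
                coalesce = False
            else:
                target_deme = 1
                coalesce = False

            kd = k0 if target_deme == 0 else k1
            if coalesce:
                # choose an unordered pair uniformly within the deme
                a_rank = np.random.randint(kd)
                b_rank = np.random.randint(kd - 1)
                if b_rank >= a_rank:
                    b_rank += 1
                a_idx = -1
                b_idx = -1
                seen = 0
                for i in range(k):
                    if deme[i] == target_deme:
                        if seen == a_rank:
                            a_idx = i
                        if seen == b_rank:
                            b_idx = i
                        seen += 1
                wd[a_idx] += wd[b_idx]
                ed[a_idx] += ed[b_idx]
                k -= 1
                deme[b_idx] = deme[k]
                wd[b_idx] = wd[k]
                ed[b_idx] = ed[k]
                if target_deme == 0:
                    k0 -= 1
                else:
                    k1 -= 1
            else:
                m_rank = np.random.randint(kd)
                seen = 0
                for i in range(k):
                    if deme[i] == target_deme:
                        if seen == m_rank:
                            deme[i] = 1 - target_deme
                            break
                        seen += 1
                if target_deme == 0:
                    k0 -= 1
                    k1 += 1
                else:
                    k1 -= 1
                    k0 += 1

        tree_lengths[s] = tot_len

    return totals, tree_lengths


def accumulate_expected_jsfs(
    model: DemographicModel,
    config: SampleConfig,
    n_sims: int,
    seed: int,
) -> BranchClassTotals:
    """Sum branch length per descendant-count class over ``n_sims`` genealogies.

    Deterministic given ``seed``.  The totals matrix, divided by its sum, is
    the Monte-Carlo estimate of the joint SFS shape conditional on
    polymorphism; ``tree_lengths`` supports absolute-scale quantities such as
    the per-site polymorphism probability.
    """
    if n_sims < 1:
        raise ModelParameterError("n_sims must be >= 1")
    totals, lengths = _simulate_batch(
        config.n_west, config.n_east,
        model.epoch_starts, model.N_west, model.N_east,
        model.m_west_east, model.m_east_west,
        model.T_div, model.N_anc,
        int(n_sims), int(seed) % (2**32),
    )
    return BranchClassTotals(totals=totals, n_genealogies=int(n_sims),
                             tree_lengths=lengths)


# --- single-genealogy path (topology retained) -----------------------------

@dataclass
class Genealogy:
    """A fully coalesced genealogy with explicit topology.

    ``node_times`` are in generations (leaves at 0); ``children[i]`` lists the
    child node ids of internal node i (empty for leaves); ``parent[i]`` is -1
    for the root.  Leaves 0..n_west-1 were sampled in the west,
    n_west..n_west+n_east-1 in the east.  ``branches`` holds per-branch
    records ``(length, n_west_desc, n_east_desc)`` for every non-root node.
    """

    n_west: int
    n_east: int
    node_times: np.ndarray
    parent: np.ndarray
    children: list[list[int]]
    leaf_sets: list[np.ndarray]

    @property
    def n_leaves(self) -> int:
        return self.n_west + self.n_east

    @property
    def branches(self) -> list[tuple[float, int, int]]:
        out = []
        for v in range(len(self.parent)):
            p = self.parent[v]
            if p < 0:
                continue
            length = float(self.node_times[p] - self.node_times[v])
            leaves = self.leaf_sets[v]
            i = int((leaves < self.n_west).sum())
            j = int(len(leaves) - i)
            out.append((length, i, j))
        return out

    @property
    def total_length(self) -> float:
        return float(sum(b[0] for b in self.branches))

    def to_newick(self) -> str:
        """Newick string with branch lengths in generations."""
        root = int(np.flatnonzero(self.parent < 0)[0])

        def fmt(v: int) -> str:
            if not self.children[v]:
                label = (f"w{v}" if v < self.n_west else f"e{v - self.n_west}")
            else:
                label = ""
            sub = label if not self.children[v] else \
                "(" + ",".join(fmt(c) + f":{self.node_times[self.parent[c]] - self.node_times[c]:.8g}"
                               for c in self.children[v]) + ")" + label
            return sub

        return fmt(root) + ";"


def simulate_genealogy(
    model: DemographicModel,
    config: SampleConfig,
    rng: np.random.Generator,
) -> Genealogy:
    """Draw one complete genealogy under the model (pure Python, topology kept).

    Same stochastic process as the batch kernel: competing exponential clocks
    for within-deme coalescence and per-lineage migration, with epoch
    boundaries and the merge treated as deterministic barriers.
    """
    n_w, n_e = config.n_west, config.n_east
    n = n_w + n_e
    # active lineage state
    node_of = list(range(n))
    deme = [0] * n_w + [1] * n_e
    times = [0.0] * n
    parent = [-1] * n
    children: list[list[int]] = [[] for _ in range(n)]
    leaf_sets: list[np.ndarray] = [np.array([i]) for i in range(n)]

    t = 0.0
    epoch = 0
    merged = False
    n_epochs = len(model.epoch_starts)

    while len(node_of) > 1:
        k0 = sum(1 for d in deme if d == 0)
        k1 = len(deme) - k0
        if merged:
            sizes = (model.N_anc, model.N_anc)
            migs = (0.0, 0.0)
            barrier = np.inf
        else:
            sizes = (model.N_west[epoch], model.N_east[epoch])
            migs = (model.m_west_east[epoch], model.m_east_west[epoch])
            barrier = (model.epoch_starts[epoch + 1]
                       if epoch + 1 < n_epochs else model.T_div)

        rates = np.array([
            k0 * (k0 - 1) / (4.0 * sizes[0]),
            k1 * (k1 - 1) / (4.0 * sizes[1]),
            k0 * migs[0],
            k1 * migs[1],
        ])
        total = rates.sum()
        dt = rng.exponential(1.0 / total) if total > 0 else np.inf

        if t + dt >= barrier:
            t = barrier
            if not merged and epoch + 1 < n_epochs:
                epoch += 1
            else:
                merged = True
                deme = [0] * len(deme)
            continue

        t += dt
        event = rng.choice(4, p=rates / total)
        target = 0 if event in (0, 2) else 1
        members = [i for i, d in enumerate(deme) if d == target]
        if event < 2:  # coalescence
            a, b = rng.choice(len(members), size=2, replace=False)
            ia, ib = members[a], members[b]
            new = len(times)
            times.append(t)
            parent.append(-1)
            children.append([node_of[ia], node_of[ib]])
            parent[node_of[ia]] = new
            parent[node_of[ib]] = new
            leaf_sets.append(np.sort(np.concatenate([leaf_sets[node_of[ia]],
                                                     leaf_sets[node_of[ib]]])))
            hi, lo = max(ia, ib), min(ia, ib)
            for idx in (hi, lo):
                node_of.pop(idx)
                deme.pop(idx)
            node_of.append(new)
            deme.append(target)
        else:  # migration
            mi = members[rng.integers(len(members))]
            deme[mi] = 1 - target

    return Genealogy(
        n_west=n_w, n_east=n_e,
        node_times=np.asarray(times),
        parent=np.asarray(parent),
        children=children,
        leaf_sets=leaf_sets,
    )
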