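"""Single-individual haplotype assembly from an allele fragment matrix.

Fragments (scaffold allele vectors over informative loci, with missing
entries) are partitioned into two sets, one per homologous chromosome, and
each side's consensus defines one haplotype. The reported objective is MEC
(minimum error correction): the number of allele calls that must be flipped
so every fragment is consistent with its assigned haplotype.

Two solvers are provided:

* ``maxcut_heuristic`` — a cut-based greedy: fragments are scored pairwise by
  (disagreements − agreements) over shared loci, bipartitioned by greedy
  single-fragment moves that increase the cut, then polished by greedy
  MEC-reducing flips; the best of ``restarts`` random initialisations wins.
* ``exhaustive`` — enumerates all bipartitions of a component (vectorised;
  intended as the small-instance oracle, <= 20 fragments).

Blocks are the connected components of the fragment–locus graph; loci in
different components cannot be phased relative to each other. Within a block
``hap1`` is the complement of ``hap0``, and the global sign is fixed by
setting the first phased allele of ``hap0`` to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FragmentMatrix", "HaplotypeBlock", "phase", "block_metrics"]


@dataclass
class FragmentMatrix:
    """Loci × fragments allele matrix in sparse form.

    ``fragments`` is a list of ``(fragment_id, {locus_index: allele})`` with
    1-based locus indices and alleles in {0, 1}. Every fragment must call at
    least two loci.
    """

    n_loci: int
    fragments: list[tuple[str, dict[int, int]]]

    def __post_init__(self) -> None:
        for fid, calls in self.fragments:
            if len(calls) < 2:
                raise ValueError(f"fragment {fid!r} has fewer than 2 called loci")
            for idx, a in calls.items():
                if not 1 <= idx <= self.n_loci:
                    raise ValueError(f"fragment {fid!r} locus index {idx} out of range")
                if a not in (0, 1):
                    raise ValueError(f"fragment {fid!r} allele {a} not in {{0,1}}")


@dataclass
class HaplotypeBlock:
    """One phased block: complementary allele vectors over a locus set."""

    locus_indices: np.ndarray  # sorted, 1-based
    hap0: np.ndarray
    hap1: np.ndarray
    mec: int
    fragment_ids: list[str]

    def __post_init__(self) -> None:
        self.locus_indices = np.asarray(self.locus_indices, dtype=np.int64)
        self.hap0 = np.asarray(self.hap0, dtype=np.int8)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)

    @property
    def n_phased(self) -> int:
        return len(self.locus_indices)


def _components(fragments) -> list[list[int]]:
    """Connected components of fragments linked by shared loci (union-find)."""
    parent = list(range(len(fragments)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    locus_owner: dict[int, int] = {}
    for fi, (_fid, calls) in enumerate(fragments):
        for locus in calls:
            if locus in locus_owner:
                ra, rb = find(locus_owner[locus]), find(fi)
                if ra != rb:
                    parent[rb] = ra
            else:
                locus_owner[locus] = fi
    groups: dict[int, list[int]] = {}
    for fi in range(len(fragments)):
        groups.setdefault(find(fi), []).append(fi)
    return sorted(groups.values(), key=lambda g: min(g))


def _component_matrix(fragments, member_idx):
    """Dense (k × m) allele matrix for one component; -1 marks missing."""
    loci = sorted({l for fi in member_idx for l in fragments[fi][1]})
    col = {l: j for j, l in enumerate(loci)}
    k, m = len(member_idx), len(loci)
    A = np.full((k, m), -1, dtype=np.int8)
    for row, fi in enumerate(member_idx):
        for l, a in fragments[fi][1].items():
            A[row, col[l]] = a
    return np.array(loci, dtype=np.int64), A


def _mec_and_hap(A: np.ndarray, side: np.ndarray) -> tuple[int, np.ndarray]:
    """MEC and consensus hap0 for a given fragment bipartition.

    Fragments on side 1 are complemented into side 0's frame before the
    per-locus majority vote; ties vote allele 0.
    """
    present = A >= 0
    B = np.where(present, A ^ side[:, None], -1)
    n1 = np.sum((B == 1), axis=0)
    n = np.sum(present, axis=0)
    mec = int(np.sum(np.minimum(n1, n - n1)))
    hap0 = (n1 * 2 > n).astype(np.int8)
    return mec, hap0


def _exhaustive(A: np.ndarray) -> tuple[int, np.ndarray]:
    """Exact minimum-MEC bipartition by enumeration (fragment 0 fixed)."""
    k, m = A.shape
    if k > 20:
        raise ValueError("exhaustive solver limited to <= 20 fragments per component")
    present = A >= 0
    # per locus, c1(mask) = ones_when_unflipped + sum_f mask_f * v_f, where
    # flipping fragment f swaps its 0/1 contribution: v = present*(1 - 2A)
    V = np.where(present, 1 - 2 * A.astype(np.int32), 0)  # k × m
    base = np.sum((A == 1), axis=0).astype(np.int32)  # m
    n = np.sum(present, axis=0).astype(np.int32)
    n_masks = 1 << (k - 1) if k > 1 else 1
    masks = ((np.arange(n_masks)[:, None] >> np.arange(k - 1)[None, :]) & 1).astype(np.int32)
    M = np.concatenate([np.zeros((n_masks, 1), dtype=np.int32), masks], axis=1)  # fragment 0 unflipped
    C1 = base[None, :] + M @ V
    mec_all = np.sum(np.minimum(C1, n[None, :] - C1), axis=1)
    best = int(np.argmin(mec_all))
    return int(mec_all[best]), M[best].astype(np.int8)


def _pair_weights(A: np.ndarray) -> np.ndarray:
    """W[i,j] = disagreements − agreements over loci shared by i and j."""
    present = (A >= 0).astype(np.int32)
    Ai = np.where(A >= 0, A, 0).astype(np.int32)
    shared = present @ present.T
    # agreements = shared loci where alleles equal
    same1 = Ai @ Ai.T  # both 1
    same0 = (present - Ai) @ (present - Ai).T  # both 0
    agree = same0 + same1
    disagree = shared - agree
    W = (disagree - agree).astype(np.int64)
    np.fill_diagonal(W, 0)
    return W


def _heuristic(A: np.ndarray, restarts: int, rng: np.random.Generator) -> tuple[int, np.ndarray]:
    """Greedy max-cut bipartition followed by greedy MEC polishing."""
    k, m = A.shape
    W = _pair_weights(A)
    present = A >= 0
    n = np.sum(present, axis=0).astype(np.int64)
    best_mec, best_side = None, None
    for _ in range(max(1, restarts)):
        side = rng.integers(0, 2, size=k).astype(np.int8)
        # phase 1: greedy cut improvement.  cut gain of flipping i is
        # sum_j W_ij * sign_i * sign_j, maintained incrementally via W @ sign
        sign = 1 - 2 * side.astype(np.int64)
        ws = W @ sign
        while True:
            gains = sign * ws
            i = int(np.argmax(gains))
            if gains[i] <= 0:
                break
            ws -= 2 * sign[i] * W[:, i]
            side[i] ^= 1
            sign[i] = -sign[i]
        # phase 2: greedy MEC-reducing single-fragment flips
        B = np.where(present, A ^ side[:, None], 0)
        n1 = np.sum(np.where(present, B, 0), axis=0).astype(np.int64)
        mec_per_locus = np.minimum(n1, n - n1)
        improved = True
        while improved:
            improved = False
            for i in range(k):
                pres_i = present[i]
                b_i = B[i]
                new_n1 = n1[pres_i] + np.where(b_i[pres_i] == 1, -1, 1)
                new_loc = np.minimum(new_n1, n[pres_i] - new_n1)
                delta = int(np.sum(new_loc) - np.sum(mec_per_locus[pres_i]))
                if delta < 0:
                    side[i] ^= 1
                    B[i, pres_i] = 1 - b_i[pres_i]
                    n1[pres_i] = new_n1
                    mec_per_locus[pres_i] = new_loc
                    improved = True
        mec = int(np.sum(mec_per_locus))
        if best_mec is None or mec < best_mec:
            best_mec, best_side = mec, side.copy()
            if best_mec == 0:
                break
    return best_mec, best_side


def phase(
    matrix: FragmentMatrix,
    algorithm: str = "maxcut_heuristic",
    restarts: int = 20,
    seed: int = 0,
) -> list[HaplotypeBlock]:
    """Assemble haplotype blocks from a fragment matrix.

    Each connected component of the fragment–locus graph yields one block.
    Identical (matrix, algorithm, restarts, seed) give identical blocks.
    """
    if algorithm not in ("maxcut_heuristic", "exhaustive"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    rng = np.random.default_rng(seed)
    blocks: list[HaplotypeBlock] = []
    for members in _components(matrix.fragments):
        loci, A = _component_matrix(matrix.fragments, members)
        if algorithm == "exhaustive":
            mec, side = _exhaustive(A)
        else:
            mec, side = _heuristic(A, restarts, rng)
        _, hap0 = _mec_and_hap(A, side)
        if hap0[0] != 0:  # canonical sign: first phased allele of hap0 is 0
            hap0 = (1 - hap0).astype(np.int8)
        blocks.append(
            HaplotypeBlock(
                locus_indices=loci,
                hap0=hap0,
                hap1=(1 - hap0).astype(np.int8),
                mec=mec,
                fragment_ids=[matrix.fragments[fi][0] for fi in members],
            )
        )
    blocks.sort(key=lambda b: int(b.locus_indices[0]))
    return blocks


def block_metrics(
    blocks: list[HaplotypeBlock],
    positions: np.ndarray,
    chrom_length: int,
    n_informative: int | None = None,
) -> dict:
    """Summary statistics of a phased block set.

    ``positions`` maps 1-based locus index i to ``positions[i-1]`` (bp).
    Block length is the span between its first and last phased locus;
    ``pct_snp_phased`` is phased loci over informative loci, and
    ``pct_genome_in_blocks`` is summed spans over the chromosome length
    (both as percentages).
    """
    positions = np.asarray(positions)
    n_inf = n_informative if n_informative is not None else len(positions)
    if not blocks:
        return {
            "mean_length": 0.0, "N50_length": 0.0, "max_length": 0.0,
            "pct_snp_phased": 0.0, "pct_genome_in_blocks": 0.0, "n_blocks": 0,
        }
    from .scaffolding import length_summary

    spans = []
    n_phased = 0
    for b in blocks:
        first, last = int(b.locus_indices[0]), int(b.locus_indices[-1])
        spans.append(max(int(positions[last - 1] - positions[first - 1]), 1))
        n_phased += b.n_phased
    summ = length_summary(spans)
    return {
        "mean_length": summ["mean"],
        "N50_length": summ["N50"],
        "max_length": summ["max"],
        "pct_snp_phased": 100.0 * n_phased / n_inf if n_inf else float("nan"),
        "pct_genome_in_blocks": 100.0 * sum(spans) / chrom_length,
        "n_blocks": len(blocks),
    }
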