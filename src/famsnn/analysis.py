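"""Post-training structure analysis.

After training, the hidden layer's learned lateral inhibition encodes which
neurons cooperate (weak mutual inhibition, near 0) and which compete
(inhibition near -1).  Treating the layer as a weighted undirected graph and
pruning edges from the most inhibitory weight upward therefore reveals a
nested hierarchy of "families" — groups of neurons that jointly encode one
input class, merging into super-groups of visually similar classes at
stronger-competition cutoffs.

This module builds that family tree, maps families to classes through the
outgoing feedforward weights, quantifies family/class agreement with the
adjusted Rand index, visualizes per-class receptive fields as the product of
the two feedforward weight matrices, measures the correlation between
forward and reciprocal hidden-output weights, and performs the reciprocal
lesion experiment (zeroing the feedback weights of a trained network).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import adjusted_rand_score

from .network import Network

__all__ = ["FamilyTree", "cluster_families", "map_families_to_classes",
           "receptive_field_product", "forward_reciprocal_correlation",
           "lesion_reciprocal", "neuron_class_labels",
           "family_class_ari", "best_cutoff_partition"]


@dataclass
class FamilyTree:
    """Nested partitions of hidden neurons across lateral-weight cutoffs.

    ``cutoffs`` ascend from -1 toward 0; at each cutoff only edges with
    symmetrized weight strictly greater than the cutoff are kept, so raising
    the cutoff can only split components, never merge them.
    """

    cutoffs: list = field(default_factory=list)
    partitions: list = field(default_factory=list)  # list[list[list[int]]]

    def n_components(self, level: int) -> int:
        return len(self.partitions[level])

    def level_with_k_components(self, k: int) -> int | None:
        """Index of the first (most negative) cutoff with exactly k families."""
        for lvl, part in enumerate(self.partitions):
            if len(part) == k:
                return lvl
        return None

    def to_json(self, path=None) -> str:
        payload = {
            "levels": [
                {"cutoff": float(c), "families": [sorted(map(int, fam))
                                                  for fam in part]}
                for c, part in zip(self.cutoffs, self.partitions)
            ]
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _labels_to_partition(labels: np.ndarray) -> list[list[int]]:
    return [sorted(np.flatnonzero(labels == c).tolist())
            for c in range(labels.max() + 1)]


def cluster_families(lateral_W: np.ndarray,
                     cutoffs: np.ndarray | None = None) -> FamilyTree:
    """Build the family tree by pruning lateral inhibition from -1 upward.

    The (possibly asymmetric) lateral matrix is symmetrized by the
    element-wise minimum (the stronger inhibition of the two directions
    wins).  For each cutoff c the graph keeps edges with weight > c and the
    connected components of that graph form the partition at level c.
    """
    W = np.asarray(lateral_W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("lateral_W must be square")
    if np.any(np.diag(W) != 0):
        raise ValueError("lateral_W must have a zero diagonal")
    if W.min() < -1 or W.max() > 0:
        raise ValueError(
            f"lateral weights must lie in [-1, 0], got range "
            f"[{W.min()}, {W.max()}]")
    if cutoffs is None:
        cutoffs = np.arange(-1.0, 0.0, 0.05)
    cutoffs = sorted(float(c) for c in cutoffs)

    sym = np.minimum(W, W.T)
    n = W.shape[0]
    tree = FamilyTree()
    for c in cutoffs:
        adj = sym > c
        np.fill_diagonal(adj, False)
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        part = [sorted(np.flatnonzero(labels == i).tolist())
                for i in range(n_comp)]
        tree.cutoffs.append(c)
        tree.partitions.append(part)
    return tree


def neuron_class_labels(W_hid_out: np.ndarray) -> np.ndarray:
    """Tag each hidden neuron with its strongest outgoing output class."""
    return np.argmax(np.asarray(W_hid_out), axis=1)


@dataclass
class FamilyClassMap:
    family_labels: list      # majority class per family
    purities: list           # majority fraction per family
    neuron_tags: np.ndarray  # per-neuron class tag used for the vote
    ari: float | None = None  # agreement with true labels, when given


def map_families_to_classes(partition: list[list[int]],
                            W_hid_out: np.ndarray,
                            true_labels: np.ndarray | None = None
                            ) -> FamilyClassMap:
    """Assign each family a class by majority vote of its neurons' tags.

    A neuron's tag is the output class receiving its strongest feedforward
    weight; the family label is the majority tag and the purity its
    fraction.  If per-neuron ground-truth labels are supplied (available for
    synthetic data), the adjusted Rand index between the partition and the
    truth is reported too.
    """
    tags = neuron_class_labels(W_hid_out)
    n = len(tags)
    covered = sorted(i for fam in partition for i in fam)
    if covered != list(range(n)):
        raise ValueError("partition must cover every hidden neuron exactly once")
    labels, purities = [], []
    for fam in partition:
        if not fam:
            raise ValueError("empty family in partition")
        votes = np.bincount(tags[fam])
        labels.append(int(np.argmax(votes)))
        purities.append(float(votes.max() / len(fam)))
    ari = None
    if true_labels is not None:
        part_labels = np.empty(n, dtype=int)
        for fid, fam in enumerate(partition):
            part_labels[fam] = fid
        ari = float(adjusted_rand_score(np.asarray(true_labels), part_labels))
    return FamilyClassMap(family_labels=labels, purities=purities,
                          neuron_tags=tags, ari=ari)


def family_class_ari(tree: FamilyTree, true_labels: np.ndarray
                     ) -> tuple[float, float]:
    """Best ARI against true labels over every cutoff, and its cutoff."""
    true_labels = np.asarray(true_labels)
    best, best_cut = -1.0, tree.cutoffs[0]
    n = len(true_labels)
    for c, part in zip(tree.cutoffs, tree.partitions):
        part_labels = np.empty(n, dtype=int)
        for fid, fam in enumerate(part):
            part_labels[fam] = fid
        ari = adjusted_rand_score(true_labels, part_labels)
        if ari > best:
            best, best_cut = float(ari), float(c)
    return best, best_cut


def best_cutoff_partition(tree: FamilyTree, k: int) -> list[list[int]]:
    """The partition at the first cutoff with k families, else the finest."""
    lvl = tree.level_with_k_components(k)
    if lvl is None:
        lvl = len(tree.partitions) - 1
    return tree.partitions[lvl]


def receptive_field_product(W_in_hid: np.ndarray, W_hid_out: np.ndarray,
                            normalize: bool = True) -> np.ndarray:
    """Per-class input-space receptive fields as a weight-matrix product.

    Returns the ``n_input x n_output`` product; each class column is min-max
    normalized for rendering when ``normalize`` is set.
    """
    W_in_hid = np.asarray(W_in_hid, dtype=float)
    W_hid_out = np.asarray(W_hid_out, dtype=float)
    if W_in_hid.shape[1] != W_hid_out.shape[0]:
        raise ValueError(
            f"shapes {W_in_hid.shape} and {W_hid_out.shape} do not compose")
    maps = W_in_hid @ W_hid_out
    if normalize:
        lo = maps.min(axis=0, keepdims=True)
        span = maps.max(axis=0, keepdims=True) - lo
        span[span == 0] = 1.0
        maps = (maps - lo) / span
    return maps


def forward_reciprocal_correlation(W_hid_out: np.ndarray,
                                   W_out_hid: np.ndarray) -> float:
    """Pearson correlation between forward and (transposed) reciprocal weights.

    Returns NaN when either matrix has zero variance (correlation undefined).
    """
    fwd = np.asarray(W_hid_out, dtype=float).ravel()
    rec = np.asarray(W_out_hid, dtype=float).T.ravel()
    if fwd.shape != rec.shape:
        raise ValueError("forward and transposed reciprocal shapes differ")
    if np.std(fwd) == 0 or np.std(rec) == 0:
        return float("nan")
    return float(np.corrcoef(fwd, rec)[0, 1])


def lesion_reciprocal(net: Network) -> Network:
    """Copy of a trained network with its feedback weights removed.

    The reciprocal weights are set to 0 and their plasticity frozen;
    everything else is untouched.  Mirrors the post-training lesion
    experiment probing how much recognition relies on output-to-hidden
    feedback.
    """
    if "rec" not in net.groups:
        raise ValueError("network has no reciprocal connection group to lesion")
    lesioned = net.copy()
    rec = lesioned.groups["rec"]
    rec.W[:] = 0.0
    rec.plastic = False
    return lesioned
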