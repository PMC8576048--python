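"""Brain parcellation model and hemispheric edge-set partitioning.

The analysis decomposes the whole-brain functional connectome into four
disjoint edge sets: intra-left-hemispheric (LH), intra-right-hemispheric
(RH), inter-hemispheric homotopic (Ho — edges linking each region to its
geometrically corresponding partner in the opposite hemisphere) and
inter-hemispheric heterotopic (He — all remaining inter-hemispheric edges).
The homotopic pairing is data, carried explicitly as ``partner_id`` in the
atlas file rather than inferred from coordinates.

A 246-region Brainnetome-style parcellation (123 regions per hemisphere:
105 cortical + 18 subcortical each side, grouped into 24 gyri and 7 lobes)
ships with the package; any atlas satisfying the same invariants works.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtlasNode",
    "Atlas",
    "AtlasValidationError",
    "Edge",
    "NetworkPartition",
    "NETWORKS",
    "load_atlas",
    "bundled_atlas_path",
    "load_bundled_atlas",
    "make_synthetic_atlas",
    "partition_edges",
    "aggregate_to_gyri",
    "write_partition",
    "GYRUS_NAMES",
    "GYRUS_ABBREVS",
    "LOBE_NAMES",
]

Edge = tuple[int, int]
Network = Literal["LH", "RH", "Ho", "He"]
NETWORKS: tuple[Network, ...] = ("LH", "RH", "Ho", "He")

ATLAS_COLUMNS = (
    "node_id",
    "name",
    "abbrev",
    "hemisphere",
    "partner_id",
    "gyrus_id",
    "lobe_id",
    "is_cortical",
)

#: Gyrus ids 1-24 of the bundled parcellation (identical in both hemispheres).
GYRUS_NAMES = {
    1: "Superior frontal gyrus", 2: "Middle frontal gyrus",
    3: "Inferior frontal gyrus", 4: "Orbital gyrus", 5: "Precentral gyrus",
    6: "Paracentral lobule", 7: "Superior temporal gyrus",
    8: "Middle temporal gyrus", 9: "Inferior temporal gyrus",
    10: "Fusiform gyrus", 11: "Parahippocampal gyrus",
    12: "Posterior superior temporal sulcus", 13: "Superior parietal lobule",
    14: "Inferior parietal lobule", 15: "Precuneus", 16: "Postcentral gyrus",
    17: "Insular gyrus", 18: "Cingulate gyrus",
    19: "Medioventral occipital cortex", 20: "Lateral occipital cortex",
    21: "Amygdala", 22: "Hippocampus", 23: "Basal ganglia", 24: "Thalamus",
}
GYRUS_ABBREVS = {
    1: "SFG", 2: "MFG", 3: "IFG", 4: "OrG", 5: "PrG", 6: "PCL", 7: "STG",
    8: "MTG", 9: "ITG", 10: "FuG", 11: "PhG", 12: "pSTS", 13: "SPL",
    14: "IPL", 15: "PCun", 16: "PoG", 17: "INS", 18: "CG", 19: "MVOcC",
    20: "LOcC", 21: "Amyg", 22: "Hipp", 23: "BG", 24: "Tha",
}
LOBE_NAMES = {
    1: "Frontal", 2: "Temporal", 3: "Parietal", 4: "Insular Lobe",
    5: "Limbic Lobe", 6: "Occipital Lobe", 7: "Subcortical Nuclei",
}


class AtlasValidationError(ValueError):
    """Raised when an atlas file violates a structural invariant."""


@dataclass(frozen=True)
class AtlasNode:
    """One parcellation region.

    ``partner_id`` names the geometrically corresponding region in the
    opposite hemisphere; the partner map must be an involution and partners
    share the same gyrus.
    """

    node_id: int
    name: str
    abbrev: str
    hemisphere: Literal["L", "R"]
    partner_id: int
    gyrus_id: int
    lobe_id: int
    is_cortical: bool


@dataclass(frozen=True)
class Atlas:
    """A validated parcellation: nodes in ascending ``node_id`` order."""

    nodes: tuple[AtlasNode, ...]

    def __post_init__(self) -> None:
        _validate_nodes(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node(self, node_id: int) -> AtlasNode:
        try:
            n = self.nodes[node_id - 1]
        except IndexError:
            raise KeyError(f"node_id {node_id} not in atlas") from None
        return n

    @property
    def nodes_per_hemisphere(self) -> int:
        return len(self.nodes) // 2

    @property
    def n_cortical(self) -> int:
        return sum(n.is_cortical for n in self.nodes)

    @property
    def abbrevs(self) -> list[str]:
        return [n.abbrev for n in self.nodes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(n) for n in self.nodes])


def _validate_nodes(nodes: Sequence[AtlasNode]) -> None:
    if not nodes:
        raise AtlasValidationError("atlas is empty")
    ids = [n.node_id for n in nodes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise AtlasValidationError(f"duplicate node_id(s): {dup}")
    if ids != list(range(1, len(nodes) + 1)):
        raise AtlasValidationError(
            "node ids must be consecutive integers 1..N in ascending order"
        )
    by_id = {n.node_id: n for n in nodes}
    n_left = sum(n.hemisphere == "L" for n in nodes)
    n_right = len(nodes) - n_left
    if n_left != n_right:
        raise AtlasValidationError(
            f"hemispheres are unbalanced: {n_left} L vs {n_right} R"
        )
    for n in nodes:
        if n.hemisphere not in ("L", "R"):
            raise AtlasValidationError(
                f"node {n.node_id}: hemisphere must be 'L' or 'R', got {n.hemisphere!r}"
            )
        partner = by_id.get(n.partner_id)
        if partner is None:
            raise AtlasValidationError(
                f"node {n.node_id}: partner_id {n.partner_id} not in atlas"
            )
        if partner.partner_id != n.node_id:
            raise AtlasValidationError(
                f"node {n.node_id}: partner map is not an involution "
                f"(partner({n.node_id})={n.partner_id} but "
                f"partner({n.partner_id})={partner.partner_id})"
            )
        if partner.hemisphere == n.hemisphere:
            raise AtlasValidationError(
                f"node {n.node_id}: partner {n.partner_id} is in the same hemisphere"
            )
        if partner.gyrus_id != n.gyrus_id:
            raise AtlasValidationError(
                f"node {n.node_id}: gyrus_id {n.gyrus_id} differs from its "
                f"partner's gyrus_id {partner.gyrus_id}"
            )


def load_atlas(path) -> Atlas:
    """Load and validate an atlas from a TSV file.

    Expected columns: ``node_id, name, abbrev, hemisphere, partner_id,
    gyrus_id, lobe_id, is_cortical``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise AtlasValidationError(f"atlas file {path} lacks column(s): {missing}")
    df = df.sort_values("node_id", kind="stable")
    nodes = tuple(
        AtlasNode(
            node_id=int(r.node_id),
            name=str(r.name),
            abbrev=str(r.abbrev),
            hemisphere=str(r.hemisphere),
            partner_id=int(r.partner_id),
            gyrus_id=int(r.gyrus_id),
            lobe_id=int(r.lobe_id),
            is_cortical=bool(int(r.is_cortical)),
        )
        for r in df.itertuples(index=False)
    )
    return Atlas(nodes)


def bundled_atlas_path():
    """Path to the packaged 246-region atlas file."""
    return importlib.resources.files("hemiconn").joinpath("data/bna246.tsv")


def load_bundled_atlas() -> Atlas:
    with importlib.resources.as_file(bundled_atlas_path()) as p:
        return load_atlas(p)


def make_synthetic_atlas(n_per_hemisphere: int, n_gyri: int | None = None) -> Atlas:
    """Build a small symmetric atlas for simulation studies and tests.

    Nodes are numbered with odd/even left/right label pairs (node ``2k-1`` is
    left, node ``2k`` its right homotope), mirroring the bundled atlas'
    convention. ``n_gyri`` gyri are assigned round-robin per homotopic pair;
    lobes cycle 1..7. The result passes the same validation as a loaded file.
    """
    if n_per_hemisphere < 1:
        raise ValueError("n_per_hemisphere must be >= 1")
    if n_gyri is None:
        n_gyri = min(n_per_hemisphere, 24)
    nodes = []
    for k in range(1, n_per_hemisphere + 1):
        gid = (k - 1) % n_gyri + 1
        lobe = (gid - 1) % 7 + 1
        left, right = 2 * k - 1, 2 * k
        for node_id, hemi, partner in ((left, "L", right), (right, "R", left)):
            nodes.append(
                AtlasNode(
                    node_id=node_id,
                    name=f"region {k} {hemi}",
                    abbrev=f"R{k}_{hemi}",
                    hemisphere=hemi,
                    partner_id=partner,
                    gyrus_id=gid,
                    lobe_id=lobe,
                    is_cortical=True,
                )
            )
    nodes.sort(key=lambda n: n.node_id)
    return Atlas(tuple(nodes))


@dataclass(frozen=True)
class NetworkPartition:
    """The four disjoint hemispheric edge sets, each sorted by (i, j).

    Edges are canonical unordered pairs ``(i, j)`` with ``i < j`` over
    1-based node ids; their union is the full upper triangle.
    """

    lh: tuple[Edge, ...]
    rh: tuple[Edge, ...]
    ho: tuple[Edge, ...]
    he: tuple[Edge, ...]

    def edges(self, network: Network) -> tuple[Edge, ...]:
        try:
            return getattr(self, network.lower())
        except AttributeError:
            raise KeyError(f"unknown network {network!r}; expected one of {NETWORKS}")

    @property
    def n_edges(self) -> int:
        return len(self.lh) + len(self.rh) + len(self.ho) + len(self.he)


def partition_edges(atlas: Atlas) -> NetworkPartition:
    """Classify every unordered region pair into LH / RH / Ho / He.

    Both endpoints left -> LH; both right -> RH; opposite hemispheres and
    homotopic partners -> Ho; other inter-hemispheric pairs -> He.
    """
    lh, rh, ho, he = [], [], [], []
    nodes = atlas.nodes
    for a in range(len(nodes)):
        na = nodes[a]
        for b in range(a + 1, len(nodes)):
            nb = nodes[b]
            e = (na.node_id, nb.node_id)
            if na.hemisphere == nb.hemisphere:
                (lh if na.hemisphere == "L" else rh).append(e)
            elif na.partner_id == nb.node_id:
                ho.append(e)
            else:
                he.append(e)
    return NetworkPartition(
        lh=tuple(sorted(lh)), rh=tuple(sorted(rh)),
        ho=tuple(sorted(ho)), he=tuple(sorted(he)),
    )


def aggregate_to_gyri(
    importances,
    atlas: Atlas,
    network: Network,
    stat: Literal["max", "mean"] = "max",
) -> pd.DataFrame:
    """Collapse edge-level importance scores onto gyrus pairs.

    Each edge maps to the unordered pair of its endpoints' gyrus ids; the
    pair score is the max (default) or mean over member edges. Returns a
    frame with columns ``gyrus_i, gyrus_j, score`` sorted by descending
    score (ties by gyrus pair).

    ``importances`` is an :class:`~hemiconn.selection.ImportanceTable` or any
    object with ``edges`` and ``importance`` attributes.
    """
    edges = importances.edges
    scores = np.asarray(importances.importance, dtype=float)
    if edges is None:
        raise ValueError("importance table carries no edge identities")
    groups: dict[tuple[int, int], list[float]] = {}
    for (i, j), x in zip(edges, scores):
        gi = atlas.node(i).gyrus_id
        gj = atlas.node(j).gyrus_id
        key = (min(gi, gj), max(gi, gj))
        groups.setdefault(key, []).append(float(x))
    agg = max if stat == "max" else (lambda v: sum(v) / len(v))
    rows = [
        {"gyrus_i": k[0], "gyrus_j": k[1], "score": agg(v)}
        for k, v in groups.items()
    ]
    df = pd.DataFrame(rows, columns=["gyrus_i", "gyrus_j", "score"])
    return df.sort_values(
        ["score", "gyrus_i", "gyrus_j"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)


def write_partition(partition: NetworkPartition, path) -> None:
    """Export the partition as TSV with columns ``network, i, j``."""
    rows: list[tuple[str, int, int]] = []
    for net in NETWORKS:
        rows.extend((net, i, j) for i, j in partition.edges(net))
    pd.DataFrame(rows, columns=["network", "i", "j"]).to_csv(
        path, sep="\t", index=False
    )
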