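"""Assembly of the tripartite herb–compound–target map and the multiscale interactome.

The multiscale interactome joins three layers: physical protein–protein
interactions, protein-to-biological-function annotations, and a
function-to-function hierarchy (child terms point at their parents).  Herbs
and compounds are not walkable nodes; they attach to the network only through
their protein target sets, which this module assembles from herb–compound and
compound–target edge tables keyed by a shared compound identifier namespace
(PubChem CIDs in practice).

Loaders accept plain TSV exports; there are no live database clients.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

NODE_KINDS = frozenset({"protein", "function", "compound", "herb", "disease"})

LAYER_NAMES = (
    "ppi",
    "protein_function",
    "function_hierarchy",
    "herb_compound",
    "compound_target",
)

#: Layers whose edges are stored undirected (canonicalized as sorted pairs).
UNDIRECTED_LAYERS = frozenset({"ppi"})


class ParseError(ValueError):
    """A malformed row in an input table, carrying the offending line number."""


class AbsentEntityError(KeyError):
    """An entity (herb/compound/disease) has no usable protein mapping."""


@dataclass(frozen=True)
class NodeRef:
    """A typed node: a stable string id plus its class in the network."""

    id: str
    kind: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass
class LayerEdges:
    """Canonicalized edge list for one layer of the multiscale network."""

    layer: str
    pairs: list[tuple[str, str]]
    directed: bool = True

    def __post_init__(self) -> None:
        if self.layer not in LAYER_NAMES:
            raise ValueError(f"unknown layer {self.layer!r}")
        self.directed = self.layer not in UNDIRECTED_LAYERS
        self.pairs = canonicalize_pairs(self.pairs, directed=self.directed)

    def __len__(self) -> int:
        return len(self.pairs)


def canonicalize_pairs(
    pairs: Iterable[tuple[str, str]], *, directed: bool
) -> list[tuple[str, str]]:
    """Collapse duplicates; undirected pairs are stored as sorted id tuples."""
    seen: dict[tuple[str, str], None] = {}
    for a, b in pairs:
        key = (a, b) if directed else (min(a, b), max(a, b))
        seen.setdefault(key, None)
    return sorted(seen)


@dataclass
class MultiscaleNetwork:
    """Typed node/edge store for the three interactome layers plus entity targets.

    ``herb_targets`` holds each herb's retained, ordered target list (the
    output of :func:`select_top_targets`); ``compound_targets`` maps each
    compound to its full mapped target set; ``herb_compounds`` records which
    compounds constitute each herb so compound-level results can be rolled
    back up to the herb.
    """

    nodes: dict[str, NodeRef] = field(default_factory=dict)
    layers: dict[str, LayerEdges] = field(default_factory=dict)
    herb_targets: dict[str, list[str]] = field(default_factory=dict)
    compound_targets: dict[str, set[str]] = field(default_factory=dict)
    herb_compounds: dict[str, set[str]] = field(default_factory=dict)

    def add_node(self, node_id: str, kind: str) -> None:
        ref = NodeRef(node_id, kind)
        existing = self.nodes.get(node_id)
        if existing is not None and existing.kind != kind:
            raise ValueError(
                f"node {node_id!r} already present with kind {existing.kind!r}"
            )
        self.nodes[node_id] = ref

    def add_layer(self, edges: LayerEdges, kinds: tuple[str, str]) -> None:
        """Attach a layer, registering endpoints under the given (src, dst) kinds."""
        src_kind, dst_kind = kinds
        for a, b in edges.pairs:
            self.add_node(a, src_kind)
            self.add_node(b, dst_kind)
        self.layers[edges.layer] = edges

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.kind == kind)

    @property
    def protein_ids(self) -> list[str]:
        return self.nodes_of_kind("protein")

    @property
    def function_ids(self) -> list[str]:
        return self.nodes_of_kind("function")

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        for edges in self.layers.values():
            for a, b in edges.pairs:
                if a not in self.nodes or b not in self.nodes:
                    raise ValueError(
                        f"edge ({a}, {b}) in layer {edges.layer} has an "
                        "unregistered endpoint"
                    )
            if edges.layer == "ppi":
                for a, b in edges.pairs:
                    if a == b:
                        raise ValueError(f"self-loop {a!r} in PPI layer")
        hierarchy = self.layers.get("function_hierarchy")
        if hierarchy is not None:
            _check_acyclic(hierarchy.pairs)
        proteins = set(self.protein_ids)
        for herb, targets in self.herb_targets.items():
            stray = set(targets) - proteins
            if stray:
                raise ValueError(f"herb {herb!r} targets outside protein nodes: {stray}")


def _check_acyclic(pairs: Sequence[tuple[str, str]]) -> None:
    """Kahn's algorithm on child→parent edges; cycles are a hard error."""
    children: dict[str, set[str]] = {}
    indegree: dict[str, int] = {}
    for child, parent in pairs:
        children.setdefault(parent, set()).add(child)
        indegree[child] = indegree.get(child, 0) + 1
        indegree.setdefault(parent, 0)
    frontier = [n for n, d in indegree.items() if d == 0]
    seen = 0
    while frontier:
        node = frontier.pop()
        seen += 1
        for child in children.get(node, ()):
            indegree[child] -= 1
            if indegree[child] == 0:
                frontier.append(child)
    if seen != len(indegree):
        raise ValueError("function hierarchy contains a cycle")


@dataclass
class CurationRules:
    """Filters applied to a disease–gene association export.

    Rows are kept only when their source is in ``allowed_sources`` (when the
    set is non-empty), their association type is not excluded, and their
    evidence class is not excluded.  ``excluded_association_types`` always
    contains ``"therapeutic"``: therapeutic annotations describe treatment
    relationships, not pathogenic mechanism, and would contaminate the seed
    set.
    """

    allowed_sources: set[str] = field(default_factory=set)
    excluded_association_types: set[str] = field(
        default_factory=lambda: {"therapeutic"}
    )
    exclude_evidence: set[str] = field(
        default_factory=lambda: {"animal_model_only", "text_mining"}
    )

    def __post_init__(self) -> None:
        self.excluded_association_types = set(self.excluded_association_types)
        self.excluded_association_types.add("therapeutic")
        self.exclude_evidence = set(self.exclude_evidence)


@dataclass
class DiseaseGeneSet:
    """Curated disease proteins restricted to the network, with provenance."""

    disease_id: str
    proteins: set[str]
    provenance: dict[str, tuple[str, str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Loading and filtering


def load_edge_table(path: str | Path, layer: str) -> LayerEdges:
    """Read a two-column TSV into a canonical :class:`LayerEdges`.

    Lines starting with ``#`` are treated as headers/comments.  Rows with
    fewer than two fields raise :class:`ParseError` naming the line number.
    Extra columns are ignored.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    n_rows = 0
    with path.open("r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(
                    f"{path}:{lineno}: expected >=2 tab-separated fields, "
                    f"got {line!r}"
                )
            pairs.append((fields[0], fields[1]))
            n_rows += 1
    edges = LayerEdges(layer=layer, pairs=pairs)
    collapsed = n_rows - len(edges)
    if n_rows == 0:
        logger.warning("%s: empty edge table for layer %s", path, layer)
    logger.info(
        "%s: %d rows -> %d canonical %s edges (%d collapsed)",
        path, n_rows, len(edges), layer, collapsed,
    )
    return edges


def filter_sparse_herbs(
    herb_compound: LayerEdges, min_compounds: int = 6
) -> LayerEdges:
    """Drop herbs annotated with fewer than ``min_compounds`` compounds.

    The default keeps herbs with six or more constituents, i.e. herbs with
    five or fewer annotated compounds are excluded along with all their
    incident edges.
    """
    if herb_compound.layer != "herb_compound":
        raise ValueError("filter_sparse_herbs expects the herb_compound layer")
    counts: dict[str, int] = {}
    for herb, _ in herb_compound.pairs:
        counts[herb] = counts.get(herb, 0) + 1
    kept = {h for h, c in counts.items() if c >= min_compounds}
    removed = len(counts) - len(kept)
    if removed:
        logger.info("filter_sparse_herbs: removed %d herbs (< %d compounds)",
                    removed, min_compounds)
    pairs = [(h, c) for h, c in herb_compound.pairs if h in kept]
    return LayerEdges(layer="herb_compound", pairs=pairs)


def merge_compound_targets(
    herb_compound: LayerEdges, compound_target: LayerEdges
) -> tuple[dict[str, dict[str, int]], dict[str, set[str]], set[str]]:
    """Join herb–compound and compound–target tables on the compound id.

    Returns ``(support, compound_targets, unmapped)`` where
    ``support[herb][protein]`` counts the herb's compounds that hit the
    protein, ``compound_targets`` maps each compound to its target set, and
    ``unmapped`` is the set of compounds with no target record.
    """
    ct: dict[str, set[str]] = {}
    for compound, protein in compound_target.pairs:
        ct.setdefault(compound, set()).add(protein)
    support: dict[str, dict[str, int]] = {}
    unmapped: set[str] = set()
    for herb, compound in herb_compound.pairs:
        targets = ct.get(compound)
        if not targets:
            unmapped.add(compound)
            continue
        counts = support.setdefault(herb, {})
        for protein in targets:
            counts[protein] = counts.get(protein, 0) + 1
    if unmapped:
        logger.info("merge_compound_targets: %d compounds had no target mapping",
                    len(unmapped))
    return support, ct, unmapped


def select_top_targets(
    herb: str,
    support_counts: Mapping[str, Mapping[str, int]],
    max_targets: int = 50,
) -> list[str]:
    """Retain the herb's top targets by supporting-compound count.

    Targets are ranked by how many of the herb's constituent compounds hit
    them (descending), with lexicographic ties on the protein id, and the
    first ``max_targets`` are kept.  The ordering is prefix-stable: raising
    the cap never reorders previously returned targets.
    """
    counts = support_counts.get(herb)
    if not counts:
        raise AbsentEntityError(f"herb {herb!r} has no mapped targets")
    ranked = sorted(counts, key=lambda p: (-counts[p], p))
    return ranked[:max_targets]


def assemble_tripartite(
    herb_compound: LayerEdges,
    compound_target: LayerEdges,
    *,
    min_compounds: int = 6,
    max_targets: int = 50,
) -> MultiscaleNetwork:
    """Run the standard herb filtering + merge + top-target pipeline.

    Produces a network fragment holding herb/compound annotations only; the
    interactome layers are attached separately with ``add_layer``.
    """
    filtered = filter_sparse_herbs(herb_compound, min_compounds=min_compounds)
    support, compound_targets, _ = merge_compound_targets(filtered, compound_target)
    net = MultiscaleNetwork()
    net.add_layer(filtered, ("herb", "compound"))
    net.add_layer(compound_target, ("compound", "protein"))
    net.compound_targets = compound_targets
    for herb, compound in filtered.pairs:
        net.herb_compounds.setdefault(herb, set()).add(compound)
    for herb in sorted(support):
        net.herb_targets[herb] = select_top_targets(
            herb, support, max_targets=max_targets
        )
    return net


def curate_disease_genes(
    rows: Iterable[Mapping[str, str]],
    rules: CurationRules,
    network: MultiscaleNetwork,
    disease_id: str = "disease",
) -> DiseaseGeneSet:
    """Apply curation rules to association rows, then restrict to network proteins.

    Each row must carry ``gene_id``, ``source``, ``association_type`` and
    ``evidence_class`` fields.  A row survives when its source is allowed (or
    no allow-list is set), its association type and evidence class are not
    excluded.  Genes whose protein is absent from the network are dropped at
    the restriction step.  An empty final set is an error: the diffusion seed
    would be undefined.
    """
    proteins = set(network.protein_ids)
    kept: set[str] = set()
    provenance: dict[str, tuple[str, str]] = {}
    for row in rows:
        gene = row["gene_id"]
        source = row.get("source", "")
        assoc = row.get("association_type", "")
        evidence = row.get("evidence_class", "")
        if rules.allowed_sources and source not in rules.allowed_sources:
            continue
        if assoc in rules.excluded_association_types:
            continue
        if evidence in rules.exclude_evidence:
            continue
        if gene not in proteins:
            continue
        kept.add(gene)
        provenance.setdefault(gene, (source, assoc))
    if not kept:
        raise ValueError(
            "disease gene curation left an empty set; "
            "no seed is available for diffusion"
        )
    return DiseaseGeneSet(disease_id=disease_id, proteins=kept, provenance=provenance)


# ---------------------------------------------------------------------------
# Bundle export / import


def write_bundle(network: MultiscaleNetwork, out_dir: str | Path) -> Path:
    """Write the network as a directory of TSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    for name, edges in sorted(network.layers.items()):
        path = out / f"{name}.tsv"
        body = "".join(f"{a}\t{b}\n" for a, b in edges.pairs)
        path.write_text(body, encoding="utf-8")
        checksums[f"{name}.tsv"] = hashlib.sha256(body.encode()).hexdigest()
    if network.herb_targets:
        rows = [
            f"{herb}\t{rank}\t{protein}\n"
            for herb in sorted(network.herb_targets)
            for rank, protein in enumerate(network.herb_targets[herb])
        ]
        body = "".join(rows)
        (out / "herb_targets.tsv").write_text(body, encoding="utf-8")
        checksums["herb_targets.tsv"] = hashlib.sha256(body.encode()).hexdigest()
    kind_counts: dict[str, int] = {}
    for node in network.nodes.values():
        kind_counts[node.kind] = kind_counts.get(node.kind, 0) + 1
    manifest = {
        "node_counts": kind_counts,
        "edge_counts": {name: len(e) for name, e in network.layers.items()},
        "checksums": checksums,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return out


_LAYER_KINDS: dict[str, tuple[str, str]] = {
    "ppi": ("protein", "protein"),
    "protein_function": ("protein", "function"),
    "function_hierarchy": ("function", "function"),
    "herb_compound": ("herb", "compound"),
    "compound_target": ("compound", "protein"),
}


def load_bundle(bundle_dir: str | Path) -> MultiscaleNetwork:
    """Re-assemble a :class:`MultiscaleNetwork` written by :func:`write_bundle`."""
    bundle = Path(bundle_dir)
    net = MultiscaleNetwork()
    for layer, kinds in _LAYER_KINDS.items():
        path = bundle / f"{layer}.tsv"
        if path.exists():
            net.add_layer(load_edge_table(path, layer), kinds)
    ct = net.layers.get("compound_target")
    if ct is not None:
        for compound, protein in ct.pairs:
            net.compound_targets.setdefault(compound, set()).add(protein)
    hc = net.layers.get("herb_compound")
    if hc is not None:
        for herb, compound in hc.pairs:
            net.herb_compounds.setdefault(herb, set()).add(compound)
    targets_path = bundle / "herb_targets.tsv"
    if targets_path.exists():
        ordered: dict[str, list[tuple[int, str]]] = {}
        with targets_path.open("r", encoding="utf-8") as handle:
            for lineno, raw in enumerate(handle, start=1):
                line = raw.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ParseError(f"{targets_path}:{lineno}: malformed row")
                herb, rank, protein = fields[0], int(fields[1]), fields[2]
                net.add_node(herb, "herb")
                net.add_node(protein, "protein")
                ordered.setdefault(herb, []).append((rank, protein))
        for herb, pairs in ordered.items():
            net.herb_targets[herb] = [p for _, p in sorted(pairs)]
    net.validate()
    return net
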