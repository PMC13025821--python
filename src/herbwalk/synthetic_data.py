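"""Synthetic multiscale networks with planted disease modules.

Real herb–compound–target compilations and the published interactome are not
redistributable, so validation runs on generated data that reproduces the
statistical structure the analysis relies on:

* a scale-free-like PPI layer (preferential attachment), emulating the heavy
  degree tail of physical interactomes;
* a rooted function hierarchy (balanced tree, child→parent edges) with
  protein–function annotations at a configurable mean rate;
* a planted disease module — a protein subset densified with extra internal
  edges — standing in for the curated disease gene neighborhood;
* *active* herbs whose targets are drawn preferentially from the module, and
  *decoy* herbs whose targets are uniform background samples, each herb's
  targets distributed over its constituent compounds.

Truth labels (active vs decoy) are returned separately from the network so
the screening pipeline never sees them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .network_model import (
    DiseaseGeneSet,
    LayerEdges,
    MultiscaleNetwork,
    assemble_tripartite,
    load_bundle,
)


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study; defaults define the benchmark conditions."""

    n_proteins: int = 500
    n_functions: int = 120
    ppi_attachment: int = 3          # preferential-attachment edges per node
    annotation_rate: float = 2.0     # mean annotations per protein
    hierarchy_branching: int = 3     # children per function term
    disease_module_size: int = 30
    module_extra_density: float = 0.2  # extra within-module edge probability
    n_active_herbs: int = 10
    n_decoy_herbs: int = 40
    targets_per_herb: int = 25
    active_overlap_fraction: float = 0.6  # share of an active herb's targets in-module
    compounds_per_herb: tuple[int, int] = (6, 15)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_functions, self.ppi_attachment,
               self.hierarchy_branching, self.disease_module_size,
               self.n_active_herbs, self.n_decoy_herbs,
               self.targets_per_herb) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.active_overlap_fraction <= 1.0:
            raise ValueError("active_overlap_fraction must lie in [0, 1]")
        if not 0.0 <= self.module_extra_density <= 1.0:
            raise ValueError("module_extra_density must lie in [0, 1]")
        if self.disease_module_size > self.n_proteins:
            raise ValueError("disease module larger than the proteome")
        lo, hi = self.compounds_per_herb
        if lo < 1 or hi < lo:
            raise ValueError("invalid compounds_per_herb range")


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def _function_id(i: int) -> str:
    return f"F{i:03d}"


def generate_network(params: GeneratorParams) -> MultiscaleNetwork:
    """Build the three interactome layers; fully reproducible from rng_seed."""
    root = np.random.SeedSequence(params.rng_seed)
    ppi_seed, annot_seed = root.spawn(2)
    rng = np.random.default_rng(annot_seed)

    # PPI: Barabasi-Albert graph over protein indices
    ba_seed = int(ppi_seed.generate_state(1)[0] % (2**31))
    g = nx.barabasi_albert_graph(params.n_proteins, params.ppi_attachment,
                                 seed=ba_seed)
    ppi_pairs = [(_protein_id(a), _protein_id(b)) for a, b in g.edges()]

    # function hierarchy: balanced tree, child -> parent
    hierarchy_pairs = [
        (_function_id(i), _function_id((i - 1) // params.hierarchy_branching))
        for i in range(1, params.n_functions)
    ]

    # annotations: Poisson(annotation_rate) function links per protein
    annot_pairs: list[tuple[str, str]] = []
    for i in range(params.n_proteins):
        n_annot = min(int(rng.poisson(params.annotation_rate)), params.n_functions)
        if n_annot == 0:
            continue
        funcs = rng.choice(params.n_functions, size=n_annot, replace=False)
        annot_pairs.extend((_protein_id(i), _function_id(int(f))) for f in funcs)

    net = MultiscaleNetwork()
    net.add_layer(LayerEdges("ppi", ppi_pairs), ("protein", "protein"))
    for i in range(params.n_proteins):  # keep isolated proteins in the index
        net.add_node(_protein_id(i), "protein")
    net.add_layer(LayerEdges("protein_function", annot_pairs),
                  ("protein", "function"))
    for i in range(params.n_functions):
        net.add_node(_function_id(i), "function")
    net.add_layer(LayerEdges("function_hierarchy", hierarchy_pairs),
                  ("function", "function"))
    net.validate()
    return net


def plant_disease_module(
    network: MultiscaleNetwork, params: GeneratorParams
) -> DiseaseGeneSet:
    """Select module proteins and densify their internal connectivity in place."""
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed).spawn(3)[2])
    proteins = network.protein_ids
    members = sorted(
        proteins[int(i)]
        for i in rng.choice(len(proteins), size=params.disease_module_size,
                            replace=False)
    )
    extra: list[tuple[str, str]] = []
    for i, a in enumerate(members):
        for b in members[i + 1:]:
            if rng.random() < params.module_extra_density:
                extra.append((a, b))
    if extra:
        ppi = network.layers["ppi"]
        network.layers["ppi"] = LayerEdges("ppi", ppi.pairs + extra)
    provenance = {p: ("CURATED", "pathogenic") for p in members}
    return DiseaseGeneSet(disease_id="hepatic_cirrhosis", proteins=set(members),
                          provenance=provenance)


def generate_herb_panel(
    network: MultiscaleNetwork,
    disease: DiseaseGeneSet,
    params: GeneratorParams,
) -> tuple[LayerEdges, LayerEdges, dict[str, str]]:
    """Herb–compound and compound–target tables plus herb truth labels.

    Active herbs draw ``active_overlap_fraction`` of their targets from the
    disease module and the rest from outside it; decoys sample all targets
    uniformly from the whole proteome (so their module overlap follows the
    hypergeometric null).  Targets are distributed over each herb's
    compounds such that every compound gets at least one target and every
    target at least one compound.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed).spawn(5)[4])
    proteins = np.array(network.protein_ids)
    module = np.array(sorted(disease.proteins))
    outside = np.array(sorted(set(network.protein_ids) - disease.proteins))

    hc_pairs: list[tuple[str, str]] = []
    ct_pairs: list[tuple[str, str]] = []
    truth: dict[str, str] = {}
    n_total = params.n_active_herbs + params.n_decoy_herbs
    lo, hi = params.compounds_per_herb
    for h in range(n_total):
        active = h < params.n_active_herbs
        herb = f"{'A' if active else 'D'}HERB{h:03d}"
        truth[herb] = "active" if active else "decoy"
        if active:
            n_module = round(params.active_overlap_fraction * params.targets_per_herb)
            picks = list(rng.choice(module, size=n_module, replace=False))
            picks += list(
                rng.choice(outside, size=params.targets_per_herb - n_module,
                           replace=False)
            )
        else:
            picks = list(
                rng.choice(proteins, size=params.targets_per_herb, replace=False)
            )
        targets = [str(t) for t in picks]
        n_compounds = int(rng.integers(lo, hi + 1))
        compounds = [f"{herb}_C{j:02d}" for j in range(n_compounds)]
        hc_pairs.extend((herb, c) for c in compounds)
        # each compound samples a random target subset; then cover leftovers
        covered: set[str] = set()
        for compound in compounds:
            size = int(rng.integers(1, max(2, len(targets) // 2)))
            subset = rng.choice(len(targets), size=size, replace=False)
            for idx in subset:
                ct_pairs.append((compound, targets[int(idx)]))
                covered.add(targets[int(idx)])
        for target in targets:
            if target not in covered:
                compound = compounds[int(rng.integers(0, n_compounds))]
                ct_pairs.append((compound, target))
    return (
        LayerEdges("herb_compound", hc_pairs),
        LayerEdges("compound_target", ct_pairs),
        truth,
    )


def generate_study(
    params: GeneratorParams | None = None,
) -> tuple[MultiscaleNetwork, DiseaseGeneSet, dict[str, str]]:
    """End-to-end synthetic study: interactome + disease module + herb panel.

    Returns the assembled network (interactome layers plus herb/compound
    target annotations run through the standard filter/merge/top-target
    pipeline), the disease gene set, and the herb truth labels.
    """
    params = params or GeneratorParams()
    network = generate_network(params)
    disease = plant_disease_module(network, params)
    hc, ct, truth = generate_herb_panel(network, disease, params)
    tripartite = assemble_tripartite(hc, ct)
    for layer_name, kinds in (("herb_compound", ("herb", "compound")),
                              ("compound_target", ("compound", "protein"))):
        network.add_layer(tripartite.layers[layer_name], kinds)
    network.herb_targets = tripartite.herb_targets
    network.compound_targets = tripartite.compound_targets
    network.herb_compounds = tripartite.herb_compounds
    network.validate()
    return network, disease, truth


def write_fixture(
    out_dir: str | Path,
    params: GeneratorParams | None = None,
) -> Path:
    """Materialize a study as the TSV bundle the loaders consume.

    Besides the network layers the bundle carries a DisGeNET-style disease
    association table (with deliberately excludable distractor rows so the
    curation rules have work to do), the truth labels, and a params manifest
    recording ``rng_seed``.
    """
    params = params or GeneratorParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network, disease, truth = generate_study(params)
    from .network_model import write_bundle

    write_bundle(network, out)

    rows = ["# gene_id\tsource\tassociation_type\tevidence_class"]
    for gene in sorted(disease.proteins):
        source, assoc = disease.provenance[gene]
        rows.append(f"{gene}\t{source}\tpathogenic\tcurated")
    # distractor rows the curation rules must drop
    outside = sorted(set(network.protein_ids) - disease.proteins)[:6]
    for i, gene in enumerate(outside):
        if i % 3 == 0:
            rows.append(f"{gene}\tCURATED\ttherapeutic\tcurated")
        elif i % 3 == 1:
            rows.append(f"{gene}\tBEFREE\tpathogenic\ttext_mining")
        else:
            rows.append(f"{gene}\tCTD\tpathogenic\tanimal_model_only")
    (out / "disease_genes.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    (out / "truth_labels.tsv").write_text(
        "".join(f"{h}\t{label}\n" for h, label in sorted(truth.items())),
        encoding="utf-8",
    )
    manifest = asdict(params)
    manifest["compounds_per_herb"] = list(params.compounds_per_herb)
    (out / "params.json").write_text(json.dumps(manifest, indent=2),
                                     encoding="utf-8")
    return out


def load_fixture(
    bundle_dir: str | Path,
) -> tuple[MultiscaleNetwork, DiseaseGeneSet, dict[str, str]]:
    """Read back a written fixture: network, curated disease set, truth labels."""
    from .network_model import CurationRules, curate_disease_genes

    bundle = Path(bundle_dir)
    network = load_bundle(bundle)
    rows = []
    with (bundle / "disease_genes.tsv").open("r", encoding="utf-8") as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            gene, source, assoc, evidence = line.split("\t")
            rows.append(
                {"gene_id": gene, "source": source,
                 "association_type": assoc, "evidence_class": evidence}
            )
    disease = curate_disease_genes(rows, CurationRules(), network,
                                   disease_id="hepatic_cirrhosis")
    truth: dict[str, str] = {}
    truth_path = bundle / "truth_labels.tsv"
    if truth_path.exists():
        for raw in truth_path.read_text(encoding="utf-8").splitlines():
            if raw.strip():
                herb, label = raw.split("\t")
                truth[herb] = label
    return network, disease, truth
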