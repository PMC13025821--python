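"""Diffusion-profile screening of herbs and compounds against a disease.

The screen follows a two-signal design: each candidate's diffusion profile
is correlated with the disease profile (ordering signal), and its target set
is tested for hypergeometric overlap with the curated disease proteins
(significance gate).  Overlap p-values are Benjamini–Hochberg corrected
across all screened entities of one kind, and a candidate is retained when
its q-value clears the threshold.  Correlation itself carries no cutoff — it
only orders the table.

At the herb level a second gate applies: a herb enters the final shortlist
only if at least ``min_active_compounds`` of its own constituent compounds
independently pass the same compound-level screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import diffusion as dfn
from .network_model import AbsentEntityError, DiseaseGeneSet, MultiscaleNetwork
from .stats import OverlapTest, bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class ScreenThresholds:
    """Retention rules for the screen."""

    q_threshold: float = 0.05
    top_n_herbs: int = 10
    min_active_compounds: int = 3

    def __post_init__(self) -> None:
        if self.q_threshold <= 0 or self.top_n_herbs <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_active_compounds < 0:
            raise ValueError("min_active_compounds must be non-negative")


@dataclass
class CandidateRecord:
    """One screened entity with its ranking statistics."""

    entity_id: str
    kind: str  # "herb" | "compound"
    correlation: float
    overlap: OverlapTest
    q_value: float = float("nan")
    retained: bool = False
    active_compound_count: int | None = None


def _entity_targets(
    entity_id: str, kind: str, network: MultiscaleNetwork
) -> set[str]:
    if kind == "herb":
        return set(network.herb_targets.get(entity_id, []))
    if kind == "compound":
        return set(network.compound_targets.get(entity_id, set()))
    raise ValueError(f"cannot screen entities of kind {kind!r}")


def screen_entities(
    entities: Sequence[str],
    kind: str,
    disease: DiseaseGeneSet,
    network: MultiscaleNetwork,
    config: dfn.DiffusionConfig | None = None,
    thresholds: ScreenThresholds | None = None,
    ts: dfn.TransitionSystem | None = None,
) -> list[CandidateRecord]:
    """Screen entities of one kind against the disease.

    Computes one diffusion profile per entity plus one for the disease,
    correlates them, runs the overlap test against the disease proteins
    (background N = interactome protein count), BH-corrects across the whole
    panel, and sorts by correlation descending with ties broken by smaller
    raw overlap p and then lexicographic id.  Entities whose seed cannot be
    resolved are skipped with a warning; an unresolvable disease seed is
    fatal.
    """
    config = config or dfn.DiffusionConfig()
    thresholds = thresholds or ScreenThresholds()
    if ts is None:
        ts = dfn.build_transition(network, config)

    disease_seed = dfn.seed_for_entity("disease", "disease", network, ts,
                                       disease=disease)
    disease_profile = dfn.diffuse(ts, disease_seed, config)
    disease_proteins = set(disease.proteins)
    n_background = sum(1 for kind_ in ts.node_kinds if kind_ == "protein")

    records: list[CandidateRecord] = []
    for entity_id in entities:
        try:
            seed = dfn.seed_for_entity(entity_id, kind, network, ts)
        except AbsentEntityError as exc:
            logger.warning("skipping %s %r: %s", kind, entity_id, exc)
            continue
        profile = dfn.diffuse(ts, seed, config)
        corr = dfn.profile_similarity(profile, disease_profile)
        targets = _entity_targets(entity_id, kind, network)
        overlap = OverlapTest.run(
            k=len(targets & disease_proteins),
            n=len(targets),
            K=len(disease_proteins),
            N=n_background,
        )
        records.append(
            CandidateRecord(entity_id=entity_id, kind=kind,
                            correlation=corr, overlap=overlap)
        )

    if records:
        q_values = bh_adjust([rec.overlap.p_value for rec in records])
        for rec, q in zip(records, q_values):
            rec.q_value = q
            rec.retained = q < thresholds.q_threshold

    records.sort(
        key=lambda rec: (-rec.correlation, rec.overlap.p_value, rec.entity_id)
    )
    return records


def mark_active_compounds(
    herb_records: Sequence[CandidateRecord],
    compound_records: Sequence[CandidateRecord],
    network: MultiscaleNetwork,
    thresholds: ScreenThresholds | None = None,
) -> list[CandidateRecord]:
    """Count each herb's retained (active) compounds.

    A compound is *active* when it was retained by the compound-level
    screen.  The count is stored on the herb record; herbs below
    ``min_active_compounds`` stay in the ranked table but become ineligible
    for :func:`final_selection`.
    """
    active = {rec.entity_id for rec in compound_records if rec.retained}
    for rec in herb_records:
        constituents = network.herb_compounds.get(rec.entity_id, set())
        rec.active_compound_count = len(constituents & active)
    return list(herb_records)


def final_selection(
    herb_records: Sequence[CandidateRecord],
    thresholds: ScreenThresholds | None = None,
) -> list[CandidateRecord]:
    """Top-N retained herbs with enough active compounds, in correlation order.

    Records must already be sorted (screen output order).  If fewer herbs are
    eligible than ``top_n_herbs``, all eligible herbs are returned and a
    notice is logged.
    """
    thresholds = thresholds or ScreenThresholds()
    eligible = [
        rec
        for rec in herb_records
        if rec.retained
        and (rec.active_compound_count or 0) >= thresholds.min_active_compounds
    ]
    if len(eligible) < thresholds.top_n_herbs:
        logger.info(
            "only %d herbs eligible (requested top %d)",
            len(eligible), thresholds.top_n_herbs,
        )
    return eligible[: thresholds.top_n_herbs]


def ranking_table(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Flatten screen records into the standard ranking table."""
    rows = []
    for rec in records:
        rows.append(
            {
                "entity": rec.entity_id,
                "kind": rec.kind,
                "correlation": rec.correlation,
                "k": rec.overlap.k,
                "n": rec.overlap.n,
                "K": rec.overlap.K,
                "N": rec.overlap.N,
                "p": rec.overlap.p_value,
                "q": rec.q_value,
                "fold_enrichment": rec.overlap.fold_enrichment,
                "neglog10_p": rec.overlap.neglog10_p,
                "retained": rec.retained,
                "active_compounds": rec.active_compound_count,
            }
        )
    return pd.DataFrame(rows)


def write_ranking(records: Sequence[CandidateRecord], path) -> None:
    """Write the ranking table as TSV with stable float formatting."""
    table = ranking_table(records)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
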