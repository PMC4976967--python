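"""End-to-end orchestration: QC → origin classification → similarity → contigs.

`Pipeline` holds the per-study state (k-mer indexes over the three databases,
coverage map, parameter sets) and classifies one sample at a time;
`analyze_study` runs every stage over a simulated study and collects the
stage outputs plus tree-recovery scores against the planted phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .classify import (
    CoverageMap,
    GenusReport,
    KmerIndex,
    MapParams,
    OriginTally,
    ReferenceSet,
    classify_sample_with_indexes,
    tallies_to_frame,
)
from .contigs import (
    ClassificationParams,
    ClassifiedContigs,
    ContigRecord,
    assembly_distance_matrix,
    classify_contigs,
    group_substrains,
)
from .formats import Anchor, ReadPair
from .qc import QcParams, QcSummary, run_qc
from .similarity import (
    Dendrogram,
    SimilarityMatrix,
    cluster_matrix,
    screen_samples,
    similarity_matrix,
    tree_recovery_score,
)
from .synthetic import ReadSimResult, SimulatedStudy, SimulationConfig


def pairs_from_sim(sim: ReadSimResult, config: SimulationConfig) -> list[ReadPair]:
    """Both-unmapped pairs of a simulated sample as pipeline-ready ReadPairs."""
    expected = (config.fragment_mean, config.insert_tolerance)
    out = []
    for m1, m2 in zip(sim.r1, sim.r2):
        pid = m1.id.split("/")[0]
        out.append(ReadPair(pid, m1, m2, config.read_length, expected))
    return out


@dataclass
class SampleResult:
    sample: str
    qc: QcSummary
    tally: OriginTally
    genus: GenusReport
    remaining: list[ReadPair]


class Pipeline:
    """Reusable per-study classifier: indexes built once, samples streamed."""

    def __init__(
        self,
        refs: ReferenceSet,
        qc_params: QcParams = QcParams(),
        map_params: MapParams = MapParams(),
    ):
        self.refs = refs
        self.qc_params = qc_params
        self.map_params = map_params
        self.alt_index = KmerIndex(refs.alternative, map_params.k_seed)
        self.y_index = (
            KmerIndex(refs.y_contigs, map_params.k_seed) if refs.y_contigs else None
        )
        self.contam_index = (
            KmerIndex(refs.contaminant, map_params.k_seed) if refs.contaminant else None
        )
        self.coverage = CoverageMap(refs.coverage)

    def run_sample(
        self,
        pairs: Sequence[ReadPair],
        half_mapped: Sequence[tuple[ReadPair, Anchor]] = (),
        sample: str = "sample",
    ) -> SampleResult:
        passing, qc_summary = run_qc(
            pairs, half_mapped, self.qc_params, self.refs.primary
        )
        tally, genus, remaining = classify_sample_with_indexes(
            passing,
            qc_summary,
            self.alt_index,
            self.y_index,
            self.contam_index,
            self.coverage,
            self.refs.taxonomy,
            self.map_params,
            sample,
        )
        return SampleResult(sample, qc_summary, tally, genus, remaining)


@dataclass
class StudyAnalysis:
    samples: dict[str, SampleResult]
    matrix: Optional[SimilarityMatrix] = None
    dendrogram: Optional[Dendrogram] = None
    similarity_rf: Optional[tuple[int, float]] = None
    contig_result: Optional[ClassifiedContigs] = None
    assembly_matrix: Optional[SimilarityMatrix] = None
    assembly_dendrogram: Optional[Dendrogram] = None
    assembly_rf: Optional[tuple[int, float]] = None

    def tally_frame(self) -> pd.DataFrame:
        return tallies_to_frame(r.tally for r in self.samples.values())


def analyze_study(
    study: SimulatedStudy,
    qc_params: QcParams = QcParams(),
    map_params: MapParams = MapParams(),
    do_similarity: bool = True,
    do_contigs: bool = True,
    min_pairs_screen: int = 1,
) -> StudyAnalysis:
    """Run all pipeline stages over a simulated study.

    ``min_pairs_screen`` replaces the real-scale 30 000-pair usability screen
    with a value matched to the simulated sample size.
    """
    pipeline = Pipeline(study.references.refs, qc_params, map_params)
    results: dict[str, SampleResult] = {}
    for name in study.strain_names:
        sim = study.reads[name]
        pairs = pairs_from_sim(sim, study.config)
        results[name] = pipeline.run_sample(pairs, sim.half_mapped, sample=name)

    analysis = StudyAnalysis(results)
    if do_similarity:
        remaining = {name: r.remaining for name, r in results.items()}
        usable, _excluded = screen_samples(remaining, min_pairs=min_pairs_screen)
        if len(usable) >= 2:
            analysis.matrix = similarity_matrix(usable)
            analysis.dendrogram = cluster_matrix(analysis.matrix)
            if len(usable) == len(remaining):
                analysis.similarity_rf = tree_recovery_score(
                    analysis.dendrogram, study.tree
                )
    if do_contigs:
        contig_map = study.contigs()
        contigs = [
            ContigRecord(c.id, strain, c.sequence)
            for strain, recs in contig_map.items()
            for c in recs
        ]
        if contigs:
            grouping = group_substrains(sorted(contig_map))
            analysis.contig_result = classify_contigs(contigs, grouping)
            assemblies = {
                strain: [ContigRecord(c.id, strain, c.sequence) for c in recs]
                for strain, recs in contig_map.items()
                if recs
            }
            if len(assemblies) >= 2:
                analysis.assembly_matrix = assembly_distance_matrix(assemblies)
                analysis.assembly_dendrogram = cluster_matrix(analysis.assembly_matrix)
                if len(assemblies) == len(contig_map):
                    analysis.assembly_rf = tree_recovery_score(
                        analysis.assembly_dendrogram, study.tree
                    )
    return analysis


def category_agreement(
    tally: OriginTally, truth: pd.DataFrame
) -> dict[str, tuple[int, int]]:
    """Per-category (observed, expected) counts of one sample.

    Expected counts come from the truth table's ``expected_category`` column.
    """
    expected = truth["expected_category"].value_counts().to_dict()
    out = {}
    for cat in tally.counts:
        out[cat] = (tally.counts.get(cat, 0), int(expected.get(cat, 0)))
    return out
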