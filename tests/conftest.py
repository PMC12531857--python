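"""Shared fixtures: hand-built toy genomes and generator-backed fixtures."""

from __future__ import annotations

import pytest

from plastcomp.genome_io import Feature, GenomeRecord
from plastcomp.simulate import PlantedSSR, SimulationSpec, simulate_genome


@pytest.fixture(scope="session")
def toy_record() -> GenomeRecord:
    """100 bp genome with a 2-exon CDS, a tRNA and a single-exon CDS.

    Layout (0-based half-open):
      geneA   gene footprint [10, 40), CDS exons [10, 20) + [30, 40)
      trnB    tRNA [50, 60)
      geneC   gene footprint [70, 80), CDS exon [70, 80)
    """
    seq = ("ACGT" * 25)[:100]
    features = [
        Feature("gene", "geneA", "+", ((10, 40),)),
        Feature("CDS", "geneA", "+", ((10, 20), (30, 40))),
        Feature("tRNA", "trnB", "+", ((50, 60),)),
        Feature("gene", "geneC", "-", ((70, 80),)),
        Feature("CDS", "geneC", "-", ((70, 80),)),
    ]
    return GenomeRecord(id="toy", sequence=seq, circular=True,
                        features=features)


@pytest.fixture(scope="session")
def small_sim():
    """Small annotated synthetic genome with planted SSRs in all three
    location classes."""
    spec = SimulationSpec(
        seed=101,
        lsc_len=12_000, ssc_len=3_000, ir_len=2_000,
        n_genes=6, n_trna=3, n_rrna=1,
        gene_len_codons=100, intron_frac=0.4, intron_len=200,
        ssr_plant_list=[
            PlantedSSR("A", 10, "IGS"),
            PlantedSSR("AT", 5, "IGS"),
            PlantedSSR("AAG", 4, "CDS"),
            PlantedSSR("T", 11, "intron"),
        ],
        genome_id="SIMSMALL",
    )
    return simulate_genome(spec)
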