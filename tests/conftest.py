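import sys
from pathlib import Path

import pytest

import panelcall as pc

sys.path.insert(0, str(Path(__file__).parent))  # for the `oracles` module


SMALL_PANEL_ROWS = [
    dict(mutation_id="KRAS G12D", gene="KRAS", amplicon_id="KRAS_G12",
         offset=61, ref_allele="G", alt_allele="A", published_lod_pct=0.020),
    dict(mutation_id="KRAS G12V", gene="KRAS", amplicon_id="KRAS_G12",
         offset=61, ref_allele="G", alt_allele="T", published_lod_pct=0.001),
    dict(mutation_id="BRAF V600E", gene="BRAF", amplicon_id="BRAF_V600",
         offset=61, ref_allele="T", alt_allele="A", published_lod_pct=0.002),
]


@pytest.fixture(scope="session")
def panel():
    return pc.load_builtin_panel()


@pytest.fixture(scope="session")
def small_panel():
    return pc.synthesize_references(SMALL_PANEL_ROWS, identifier_len=8, seed=3)


@pytest.fixture(scope="session")
def clean_sim(small_panel):
    """Noise-free simulated sample (no PCR/sequencing errors, no enrichment)."""
    cfg = pc.SimConfig(
        input_genomes=500,
        mutant_copies={"KRAS G12D": 20},
        ipc_copies=30,
        per_base_error_per_cycle=0.0,
        retain_mut=0.9,
        retain_wt=0.9,
        enrich_cycles=4,
        reads_per_sample=6000,
        seed=11,
    )
    return pc.simulate_sample(small_panel, cfg)


@pytest.fixture(scope="session")
def clean_clusters(small_panel, clean_sim):
    clusters, qc = pc.process_pool(
        clean_sim.r1, clean_sim.r2, small_panel, {"S1": clean_sim.config.barcode}
    )
    return clusters, qc
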