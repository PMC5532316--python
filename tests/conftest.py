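import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import lncsig as L


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast study: fewer genes and drugs than the package defaults."""
    return L.FixtureSpec(
        seed=11,
        n_lnc_genes=12,
        n_coding_genes=6,
        probes_per_gene=5,
        n_decoy_probes=4,
        n_drugs=4,
        instances_per_drug=2,
        effect_genes_per_drug=4,
    )


@pytest.fixture(scope="session")
def pipeline_bundle(small_spec):
    """One full synthetic pipeline run shared by read-only tests."""
    spec = small_spec
    transcripts = L.simulate_transcriptome(spec)
    probes, transcripts, truth = L.simulate_probes(transcripts, spec)
    remap = L.build_reannotation(probes, transcripts)
    matrix, instances = L.simulate_instances(truth, spec)
    gene_matrix = L.summarize_gene_expression(matrix, remap)
    sigs = L.build_signatures(gene_matrix, instances)
    drug_sets = L.build_drug_sets(sigs, instances)
    return {
        "spec": spec,
        "transcripts": transcripts,
        "probes": probes,
        "truth": truth,
        "remap": remap,
        "matrix": matrix,
        "instances": instances,
        "gene_matrix": gene_matrix,
        "signatures": sigs,
        "drug_sets": drug_sets,
    }
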