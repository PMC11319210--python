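"""Shared fixtures: all synthetic inputs are generated at test time."""

import numpy as np
import pytest

from panscape import (AncestryDesign, cluster_monomers, find_tandem_repeats,
                      merge_svs, simulate_chromosome, simulate_pav,
                      simulate_sv_landscape)

SEED = 1


@pytest.fixture(scope="session")
def small_pav():
    pav, manifest = simulate_pav(n_accessions=6, n_families=300, seed=SEED)
    return pav, manifest


@pytest.fixture(scope="session")
def study_panel_pav():
    """28 accessions, study-like class mix, enough families for recovery."""
    return simulate_pav(n_accessions=28, n_families=20_000,
                        class_proportions=(0.43, 0.09, 0.46, 0.02),
                        seed=SEED)


@pytest.fixture(scope="session")
def simulated_chromosome():
    """One 400-kb chromosome with a centromeric array at 5% divergence."""
    seq, bundle, manifest = simulate_chromosome(
        length=400_000, centromere_span=(160_000, 240_000), seed=SEED)
    return seq, bundle, manifest


@pytest.fixture(scope="session")
def detected_arrays(simulated_chromosome):
    seq, _, _ = simulated_chromosome
    arrays = find_tandem_repeats(seq, chromosome="chr01")
    clusters = cluster_monomers(arrays)
    return arrays, clusters


@pytest.fixture(scope="session")
def sv_world():
    """A 2-Mb annotated chromosome plus a 5-accession SV landscape."""
    _, bundle, _ = simulate_chromosome(
        length=2_000_000, centromere_span=(800_000, 1_000_000), seed=SEED)
    accessions = ["t1", "t2", "t3", "anc_a", "anc_b"]
    design = AncestryDesign(target_group=("t1", "t2", "t3"),
                            ancestor_a="anc_a", ancestor_b="anc_b")
    calls, manifest = simulate_sv_landscape(
        accessions, design, n_svs=2_000, repeat_enrichment_factor=3.0,
        annotation_bundle=bundle, seed=SEED)
    merged = merge_svs(calls)
    return bundle, design, calls, manifest, merged
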