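import numpy as np
import pytest

import insmap as im


def random_genome(seed: int, lengths=(50_000, 30_000), gc: float = 0.5) -> im.GenomeIndex:
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {
        f"chr{i + 1}": "".join(
            np.array(list("ACGT"))[rng.choice(4, size=L, p=probs)]
        )
        for i, L in enumerate(lengths)
    }
    return im.GenomeIndex(seqs)


@pytest.fixture(scope="session")
def toy_genome() -> im.GenomeIndex:
    return random_genome(11)


@pytest.fixture(scope="session")
def sim_bundle():
    """A small simulated study shared by the analysis-level tests."""
    cfg = im.SimulationConfig(
        seed=5,
        chromosome_lengths=(300_000, 200_000),
        n_genes=25,
        gene_mean_length=3_000,
        n_sites=600,
        n_peaks=40,
        n_enhancers=20,
        n_super_enhancers=5,
        super_enhancer_width=(4_000, 8_000),
    )
    genome, genes, tracks = im.simulate_genome(cfg)
    iset, labels = im.simulate_insertions(genome, genes, tracks, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "tracks": tracks,
        "sites": iset,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def sim_shear_controls(sim_bundle):
    motif = im.scan_motif_positions(sim_bundle["genome"], "TTAA")
    return im.generate_shear_controls(
        sim_bundle["sites"], sim_bundle["genome"], motif=motif, n_sets=40, seed=9
    )
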