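import numpy as np
import pytest

from longbin.embed import VAEConfig, encode, train_vae
from longbin.features import assemble_features
from longbin.simdata import CommunitySpec, generate_genomes, simulate_reads


@pytest.fixture(scope="session")
def three_species_community():
    """A 3-species community with 5x/25x/100x abundance spread, fully featurised
    and embedded; shared by the embedding-quality tests."""
    spec = CommunitySpec(n_species=3, n_reads=3000, abundances=[5, 25, 100], seed=0)
    genomes = generate_genomes(spec)
    reads, truth = simulate_reads(genomes, spec)
    features, read_ids, _ = assemble_features(reads)
    model, trace = train_vae(features, VAEConfig(epochs=100, seed=0))
    latent = encode(features, model)
    labels = np.array([truth[r] for r in read_ids])
    return {
        "spec": spec,
        "reads": reads,
        "truth": truth,
        "features": features,
        "read_ids": read_ids,
        "latent": latent,
        "labels": labels,
        "trace": trace,
    }


def make_blobs(sizes, spread, rng, dim=8, min_sep=0.5):
    """Well-separated cosine blobs: unit centres with pairwise cosine distance
    >= min_sep, members = centre + Gaussian noise of the given spread."""
    centres = []
    while len(centres) < len(sizes):
        c = rng.standard_normal(dim)
        c /= np.linalg.norm(c)
        if all(1 - c @ o > min_sep for o in centres):
            centres.append(c)
    points, labels = [], []
    for i, (c, n) in enumerate(zip(centres, sizes)):
        points.append(c + spread * rng.standard_normal((n, len(c))))
        labels.append(np.full(n, i))
    order = rng.permutation(sum(sizes))
    return np.vstack(points)[order], np.concatenate(labels)[order]
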