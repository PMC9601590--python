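import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitochar as mc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template_genome():
    """One synthetic genome built from the default architecture template."""
    genome, truth = mc.generate_mitogenome(seed=1)
    return genome, truth


@pytest.fixture(scope="session")
def organization_rows(template_genome):
    genome, _ = template_genome
    return mc.build_gene_table(genome)


def random_additive_distances(n_taxa: int, rng: np.random.Generator):
    """Distances generated by a random binary tree (additive by construction).

    Returns (labels, matrix). Branch lengths are bounded away from zero so
    the generating topology is uniquely recoverable.
    """
    nodes = [(f"t{i:02d}", {f"t{i:02d}": 0.0}) for i in range(n_taxa)]
    dist: dict[frozenset, float] = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (_, da), (_, db) = nodes[i], nodes[j]
        ba, bb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[frozenset((x, y))] = dx + ba + bb + dy
        merged = {x: dx + ba for x, dx in da.items()}
        merged.update({y: dy + bb for y, dy in db.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [("", merged)]
    labels = sorted({x for pair in dist for x in pair})
    m = np.zeros((len(labels), len(labels)))
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            m[a, b] = m[b, a] = dist[frozenset((labels[a], labels[b]))]
    return labels, m


def tree_path_distances(newick: str):
    """Leaf-to-leaf path lengths of a Newick tree, via dendropy (oracle)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    out = {}
    labels = sorted(taxa)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            out[(labels[a], labels[b])] = pdm.distance(taxa[labels[a]], taxa[labels[b]])
    return out
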