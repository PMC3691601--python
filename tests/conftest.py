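"""Shared fixtures: a study-scale synthetic panel built once per session.

The panel emulates the cross the package targets: 160 F2 males, 22
chromosomes totalling 1,933 cM, ~834 codominant markers, per-individual
missingness averaging ~182 calls, and eleven phenotype columns of which
three carry a QTL (two sharing a locus) at realistic variance fractions.
"""

import numpy as np
import pytest

import crossqtl as cq

STUDY_SEED = 1

# trait architectures: (name, target PVE, dominance ratio d/a, chrom, cM, sign)
STUDY_QTL_TRAITS = [
    ("dorsal_fin_xanthophores", 0.274, 0.5, "LG12", 67.0, +1),
    ("caudal_fin_xanthophores", 0.140, 1.0, "LG12", 67.0, +1),
    ("pelvic_fin_melanophores", 0.134, 0.0, "LG11", 75.0, -1),
]
STUDY_NULL_TRAITS = [
    "bar_melanophores", "interbar_melanophores", "dorsal_fin_melanophores",
    "caudal_fin_melanophores", "cheek_melanophores", "pelvic_yellow_score",
    "gular_yellow_score", "pc1",
]


def study_trait_architectures():
    traits = []
    for name, pve_t, dom_ratio, chrom, pos, sign in STUDY_QTL_TRAITS:
        a, d = cq.target_pve_to_effect(pve_t, dom_ratio, 1.0)
        traits.append(
            cq.TraitArchitecture(name, qtls=[(chrom, pos, sign * a, d)], sigma_e=1.0)
        )
    for name in STUDY_NULL_TRAITS:
        traits.append(cq.TraitArchitecture(name, qtls=[], sigma_e=1.0))
    return traits


@pytest.fixture(scope="session")
def study_panel():
    """Simulated study-conditions cross: (genotypes, phenotypes, truth)."""
    cfg = cq.CrossConfig(seed=STUDY_SEED)
    return cq.simulate_cross(cfg, study_trait_architectures())


@pytest.fixture(scope="session")
def study_map(study_panel):
    """Linkage map fitted to the study panel (LOD >= 5 grouping, Kosambi)."""
    g, _, _ = study_panel
    return cq.LinkageMapper(g, lod_min=5.0, r_max=0.45).fit()


@pytest.fixture(scope="session")
def study_probs(study_panel, study_map):
    """Genotype probabilities on the fitted map, 1 cM grid."""
    g, _, _ = study_panel
    g_m = g.subset_markers(list(study_map.map.table.index))
    return g_m, cq.calc_genoprob(g_m, study_map.map, step_cm=1.0, error_rate=1e-4)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
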