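import numpy as np
import pytest

from kellvar.catalog import load_catalog
from kellvar.properties import load_packaged_scales
from kellvar.structure import build_residue_contexts, read_structure
from kellvar.synthetic import SyntheticSpec, generate_msa, generate_structure


@pytest.fixture(scope="session")
def catalog():
    """The packaged Kell variant tables, parsed and merged."""
    return load_catalog()


@pytest.fixture(scope="session")
def scales():
    return load_packaged_scales()


@pytest.fixture(scope="session")
def toy_spec():
    """Small structure plan with all three burial classes."""
    return SyntheticSpec(
        n_residues=66,
        seed=11,
        burial_plan={
            61: "buried",
            62: "buried",
            63: "half_buried",
            64: "exposed",
            65: "exposed",
            66: "exposed",
        },
        conservation_plan={61: 100.0, 63: 66.0, 64: 33.0, 66: 0.0},
        residue_types={61: "L", 62: "W", 63: "T", 64: "R", 65: "L", 66: "E"},
    )


@pytest.fixture(scope="session")
def toy_structure_path(toy_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("structure") / "toy.pdb"
    generate_structure(toy_spec, path)
    return path


@pytest.fixture(scope="session")
def toy_contexts(toy_structure_path):
    residues = read_structure(toy_structure_path)
    return build_residue_contexts(residues)


@pytest.fixture(scope="session")
def toy_alignment_path(toy_spec, tmp_path_factory):
    path = tmp_path_factory.mktemp("msa") / "toy.fasta"
    generate_msa(toy_spec, n_orthologs=39, path=path)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)
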