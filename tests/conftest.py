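import numpy as np
import pytest

import fiberdiff as fd

PDB_TEMPLATE = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{resseq:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def make_pdb(path, atoms):
    """Write a minimal PDB file; atoms = [(element, name, x, y, z), ...]."""
    lines = []
    for i, (element, name, x, y, z) in enumerate(atoms, start=1):
        lines.append(
            PDB_TEMPLATE.format(
                serial=i, name=name, alt=" ", res="ALA", chain="A", resseq=1,
                x=x, y=y, z=z, occ=1.0, b=0.0, element=element,
            )
        )
    lines.append("END\n")
    path.write_text("".join(lines))
    return path


@pytest.fixture
def cno_pdb(tmp_path):
    """Three heavy atoms (C, N, O) plus two hydrogens."""
    return make_pdb(
        tmp_path / "cno.pdb",
        [
            ("C", "CA", 16.2, 0.0, 5.0),
            ("N", "N", 0.0, 0.0, 2.0),
            ("O", "O", -3.0, 4.0, -1.0),
            ("H", "H1", 1.0, 1.0, 1.0),
            ("H", "H2", 2.0, 2.0, 2.0),
        ],
    )


@pytest.fixture(scope="session")
def small_monomer():
    """A 200-atom seeded synthetic monomer (fast coarse-grain tests)."""
    return fd.generate_synthetic_monomer(n_atoms=200, seed=11)


@pytest.fixture(scope="session")
def actin_monomer():
    """Full-size synthetic actin-like monomer (2991 heavy atoms)."""
    return fd.generate_synthetic_monomer(seed=1)


def random_sites(seed, n_sites=None, r0_max=30.0):
    """Random small ScattererSet for oracle comparisons."""
    rng = np.random.default_rng(seed)
    if n_sites is None:
        n_sites = int(rng.integers(1, 6))
    return fd.ScattererSet(
        r0=rng.uniform(0.0, r0_max, n_sites),
        psi1=rng.uniform(0.0, 2 * np.pi, n_sites),
        z1=rng.uniform(-12.0, 12.0, n_sites),
        rs=rng.uniform(1.0, 8.0, n_sites),
        weight=rng.uniform(5.0, 20.0, n_sites),
    )
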