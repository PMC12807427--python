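import numpy as np
import pytest

from ythdyn import synthetic


def _pdb_atom(serial, name, res, chain, resseq, xyz, element, altloc=" "):
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5} {name:<4}{altloc}{res:>3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


@pytest.fixture(scope="session")
def three_model_pdb(tmp_path_factory):
    """Hand-written 3-model PDB: one ALA residue plus one adenosine,
    with a hydrogen on each to exercise heavy-atom filtering."""
    atoms = [
        ("N", "ALA", "A", 347, "N"),
        ("CA", "ALA", "A", 347, "C"),
        ("CB", "ALA", "A", 347, "C"),
        ("H", "ALA", "A", 347, "H"),
        ("N9", "A", "B", 3, "N"),
        ("C8", "A", "B", 3, "C"),
        ("H8", "A", "B", 3, "H"),
    ]
    base = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [2.0, 1.3, 0.2],
            [-0.6, 0.8, 0.1],
            [4.0, 2.0, 1.0],
            [5.1, 2.5, 1.2],
            [5.8, 3.2, 1.5],
        ]
    )
    lines = []
    for m in range(1, 4):
        lines.append(f"MODEL     {m:>4}")
        shift = np.array([0.0, 0.0, float(m - 1)])  # models differ along z
        for i, (name, res, chain, resseq, elem) in enumerate(atoms):
            lines.append(
                _pdb_atom(i + 1, name, res, chain, resseq, base[i] + shift, elem)
            )
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path_factory.mktemp("pdb") / "three_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture(scope="session")
def template_spec():
    return synthetic.ComplexTemplate(seed=0)


@pytest.fixture(scope="session")
def template(template_spec):
    return synthetic.build_template(template_spec)


@pytest.fixture(scope="session")
def two_state_run(template, template_spec):
    """Two-state ensemble at the default study conditions (3 x 1000 frames)."""
    dyn = synthetic.DynamicsSpec(seed=7)
    return synthetic.generate_trajectories(template, template_spec, dyn,
                                           "two_state")
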