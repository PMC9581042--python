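"""Synthetic inputs for building and testing the scorer without downloads.

The generators produce idealized but structurally valid complexes: a
helical receptor with a contact face, an extended peptide placed against
it, rigid-body decoy sets with analytically controlled LRMSD, mutational
toy alignments, and a "planted-signal" labeled dataset in which correct
decoys keep native-like contact patterns while incorrect decoys bind the
opposite face of the receptor — a geometric signal a small network can
learn.  Everything is deterministic under its seed.

These fixtures emulate the *geometry and bookkeeping* of rigid-body
docking output, not its energetics: no side chains beyond the backbone,
no steric refinement, no peptide conformer resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .evolution_features import (
    AA20,
    MultipleSequenceAlignment,
    background_frequencies,
    compute_profile,
)
from .graph import DecoyGraph, featurize_decoy
from .structure_io import (
    ComplexStructure,
    ResidueRecord,
    _contact_pairs,
    compute_lrmsd,
    write_pdb,
)
from .training import LabeledDecoy

_BOND_CA_OFFSET = 1.2   # N/C placement along the chain direction (Å)
_CO_LENGTH = 1.23       # carbonyl O offset from C (Å)
_CONTACT_DISTANCE = 4.0  # native peptide-receptor closest approach (Å)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic benchmark target."""

    receptor_len: int = 55
    peptide_len: int = 8
    n_decoys: int = 100
    lrmsd_targets: tuple[float, ...] | None = None
    msa_depth: int = 20
    mutation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.receptor_len < 2 or self.peptide_len < 2:
            raise ValueError("chains need at least two residues")
        if self.peptide_len > 25:
            raise ValueError("peptide length must be <= 25")
        if self.n_decoys < 1 or self.msa_depth < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must be in [0, 1)")


def _aa3(aa1: str) -> str:
    return protein_letters_1to3.get(aa1, "Unk").upper()


def _backbone_residues(
    ca: np.ndarray, sequence: str, chain_id: str
) -> list[ResidueRecord]:
    """Backbone (N, CA, C, O) residues threaded along a CA trace.

    N and C are placed along the chain direction so that consecutive C-N
    distances stay under the 2 Å peptide-bond cutoff; O hangs off C
    perpendicular to the chain.
    """
    n = len(ca)
    residues = []
    for i in range(n):
        d_prev = ca[i] - ca[i - 1] if i > 0 else ca[i + 1] - ca[i]
        d_next = ca[i + 1] - ca[i] if i < n - 1 else ca[i] - ca[i - 1]
        d_prev = d_prev / np.linalg.norm(d_prev)
        d_next = d_next / np.linalg.norm(d_next)
        n_pos = ca[i] - _BOND_CA_OFFSET * d_prev
        c_pos = ca[i] + _BOND_CA_OFFSET * d_next
        perp = np.cross(d_next, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(d_next, [1.0, 0.0, 0.0])
        perp = perp / np.linalg.norm(perp)
        o_pos = c_pos + _CO_LENGTH * perp
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                res_seq=i + 1,
                icode="",
                aa3=_aa3(sequence[i]),
                aa1=sequence[i],
                heavy_atoms=[
                    ("N", *map(float, n_pos)),
                    ("CA", *map(float, ca[i])),
                    ("C", *map(float, c_pos)),
                    ("O", *map(float, o_pos)),
                ],
            )
        )
    return residues


def _helix_ca(n: int, radius: float = 2.3, rise: float = 1.5, phase: float = 0.0):
    t = np.arange(n) * np.deg2rad(100.0) + phase
    return np.stack(
        [radius * np.cos(t), radius * np.sin(t), np.arange(n) * rise], axis=1
    )


def _strand_ca(n: int, spacing: float = 3.8):
    return np.stack(
        [np.zeros(n), np.zeros(n), np.arange(n) * spacing], axis=1
    )


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


#: Residue alphabets of the two receptor faces: the binding face is
#: hydrophobic (as peptide-binding grooves tend to be), the rest polar/charged.
_FACE_HYDROPHOBIC = "LIVFM"
_FACE_POLAR = "KEDRSTNQ"


def binding_face_mask(n: int, phase: float = 0.0) -> np.ndarray:
    """Receptor positions whose helix side chains face the bound peptide (+x)."""
    t = np.arange(n) * np.deg2rad(100.0) + phase
    return np.cos(t) > 0.3


def _receptor_sequence(rng: np.random.Generator, n: int) -> str:
    """Helix sequence with a hydrophobic binding face and polar elsewhere."""
    face = binding_face_mask(n)
    letters = [
        rng.choice(list(_FACE_HYDROPHOBIC)) if face[i] else rng.choice(list(_FACE_POLAR))
        for i in range(n)
    ]
    return "".join(letters)


def make_toy_complex(spec: FixtureSpec, complex_id: str = "toy") -> ComplexStructure:
    """Native complex: helical receptor with an extended peptide bound at its face.

    The peptide runs parallel to the receptor helix axis, centered on the
    helix, and is translated until its closest heavy-atom approach equals
    4.0 Å, guaranteeing a non-empty native interface under the 4.5 Å
    proximity cutoff.  The receptor face toward the peptide is hydrophobic
    and the rest polar, mimicking a peptide-binding groove.
    """
    rng = np.random.default_rng(spec.seed)
    rec_seq = _receptor_sequence(rng, spec.receptor_len)
    pep_seq = _random_sequence(rng, spec.peptide_len)

    rec_ca = _helix_ca(spec.receptor_len)
    receptor = _backbone_residues(rec_ca, rec_seq, "A")
    rec_coords = np.concatenate([r.coords() for r in receptor], axis=0)

    pep_ca = _strand_ca(spec.peptide_len)
    z_mid = rec_ca[:, 2].mean() - pep_ca[:, 2].mean()
    pep_ca = pep_ca + np.array([8.0, 0.0, z_mid])
    # slide along +x until the closest heavy-atom pair sits at 4.0 A
    for _ in range(8):
        peptide = _backbone_residues(pep_ca, pep_seq, "B")
        pep_coords = np.concatenate([r.coords() for r in peptide], axis=0)
        d = np.sqrt(
            np.min(
                np.sum((pep_coords[:, None, :] - rec_coords[None, :, :]) ** 2, axis=-1)
            )
        )
        if abs(d - _CONTACT_DISTANCE) < 1e-6:
            break
        pep_ca = pep_ca + np.array([_CONTACT_DISTANCE - d, 0.0, 0.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ComplexStructure(receptor=receptor, peptide=peptide, id=complex_id)


def _transform_peptide(
    native: ComplexStructure,
    rotation: np.ndarray | None,
    translation: np.ndarray,
    decoy_id: str,
) -> ComplexStructure:
    """Decoy = native with the peptide rigidly transformed (receptor fixed)."""
    atoms = np.concatenate([r.coords() for r in native.peptide], axis=0)
    centroid = atoms.mean(axis=0)
    new_pep = []
    for res in native.peptide:
        moved = []
        for name, x, y, z in res.heavy_atoms:
            v = np.array([x, y, z]) - centroid
            if rotation is not None:
                v = rotation @ v
            v = v + centroid + translation
            moved.append((name, float(v[0]), float(v[1]), float(v[2])))
        new_pep.append(
            ResidueRecord(res.chain_id, res.res_seq, res.icode, res.aa3, res.aa1, moved)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ComplexStructure(receptor=native.receptor, peptide=new_pep, id=decoy_id)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


def make_decoy_set(
    native: ComplexStructure,
    lrmsd_targets,
    seed: int,
    mode: str = "translation",
    tolerance: float = 0.10,
    max_retries: int = 20,
) -> list[tuple[ComplexStructure, float]]:
    """Rigid-perturbation decoys hitting the requested LRMSD values.

    ``translation`` mode moves the peptide along a random direction by
    exactly the target distance (LRMSD equals the translation length after
    the receptor superposition, which is the identity here).  ``mixed``
    mode composes a random rotation about the peptide centroid with a
    translation solved analytically so the combined backbone RMSD hits the
    target; each decoy is verified against :func:`compute_lrmsd` and
    rejected if off by more than ``tolerance``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for k, target in enumerate(lrmsd_targets):
        if target < 0:
            raise ValueError("LRMSD targets must be non-negative")
        decoy_id = f"{native.id}_d{k:04d}"
        for attempt in range(max_retries):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            if mode == "translation" or target == 0:
                decoy = _transform_peptide(native, None, direction * target, decoy_id)
            elif mode == "mixed":
                bb = np.concatenate([r.coords() for r in native.peptide], axis=0)
                centered = bb - bb.mean(axis=0)
                angle = np.deg2rad(rng.uniform(5.0, 25.0))
                for _ in range(30):
                    R = _rotation_matrix(rng.normal(size=3), angle)
                    disp = centered @ (R - np.eye(3)).T
                    rms_rot = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
                    if rms_rot <= target:
                        break
                    angle *= 0.5
                else:
                    continue
                t_len = np.sqrt(max(target**2 - rms_rot**2, 0.0))
                decoy = _transform_peptide(native, R, direction * t_len, decoy_id)
            else:
                raise ValueError(f"unknown mode '{mode}'")
            achieved = compute_lrmsd(decoy, native)
            ok = (
                abs(achieved - target) <= tolerance * max(target, 1e-9)
                or abs(achieved - target) < 1e-6
            )
            if ok:
                # pure translations hit the target analytically; report the
                # exact value so threshold comparisons are not perturbed by
                # superposition round-off
                if mode == "translation" and abs(achieved - target) < 1e-6:
                    achieved = float(target)
                out.append((decoy, achieved))
                break
        else:
            raise RuntimeError(
                f"could not reach LRMSD target {target} within {max_retries} tries"
            )
    return out


def make_opposite_face_decoy(
    native: ComplexStructure, seed: int, decoy_id: str
) -> tuple[ComplexStructure, float]:
    """An incorrect decoy binding the opposite face of the receptor.

    The peptide is mirrored through the receptor helix axis (x -> -x about
    the receptor centroid) and jittered, so it contacts a different
    receptor face at LRMSD far beyond the 4 Å correctness limit.
    """
    rng = np.random.default_rng(seed)
    rec_coords = np.concatenate([r.coords() for r in native.receptor], axis=0)
    cx = rec_coords[:, 0].mean()
    pep = np.concatenate([r.coords() for r in native.peptide], axis=0)
    centroid = pep.mean(axis=0)
    target = np.array([2 * cx - centroid[0], centroid[1], centroid[2]])
    shift = target - centroid + rng.normal(scale=1.0, size=3)
    decoy = _transform_peptide(native, None, shift, decoy_id)
    return decoy, compute_lrmsd(decoy, native)


def make_toy_msa(
    query: str,
    depth: int,
    mutation_rate,
    seed: int,
    gap_rate: float = 0.0,
) -> MultipleSequenceAlignment:
    """Mutational alignment: rows are point-mutated copies of the query.

    ``mutation_rate`` may be a scalar or a per-position array (conserved
    columns get low rates).  Substitutions are drawn from the BLOSUM62
    amino-acid background, so at mutation rate -> 1 the column frequencies
    approach the background distribution.  Optional uniform gap injection.
    Row 0 is the query.
    """
    rate = np.broadcast_to(np.asarray(mutation_rate, dtype=float), (len(query),))
    if np.any(rate < 0) or np.any(rate > 1):
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bg = background_frequencies()[:20]
    bg = bg / bg.sum()
    letters = np.array(list(AA20))
    rows = [query]
    for _ in range(depth - 1):
        chars = np.array(list(query))
        mut = rng.random(len(query)) < rate
        chars[mut] = rng.choice(letters, size=int(mut.sum()), p=bg)
        if gap_rate > 0:
            gaps = rng.random(len(query)) < gap_rate
            chars[gaps] = "-"
        rows.append("".join(chars))
    return MultipleSequenceAlignment(query=query, rows=rows)


# ---------------------------------------------------------------------------
# planted-signal dataset


@dataclass
class PlantedDataset:
    """Labeled decoy graphs with a built-in learnable geometric signal."""

    graphs: list[DecoyGraph]
    labels: list[LabeledDecoy]
    natives: dict[str, ComplexStructure] = field(default_factory=dict)

    def lrmsd(self) -> np.ndarray:
        return np.array([l.lrmsd for l in self.labels])

    def target_ids(self) -> np.ndarray:
        return np.array([l.target_id for l in self.labels])

    def subset(self, indices) -> "PlantedDataset":
        return PlantedDataset(
            graphs=[self.graphs[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            natives=self.natives,
        )

    def split_by_targets(self, target_sets: list[set]) -> list["PlantedDataset"]:
        """Partition by disjoint target-id sets (grouped split)."""
        seen = [t for s in target_sets for t in s]
        if len(seen) != len(set(seen)):
            raise ValueError("target sets overlap")
        parts = []
        for s in target_sets:
            idx = [i for i, l in enumerate(self.labels) if l.target_id in s]
            parts.append(self.subset(idx))
        return parts


def make_planted_target(
    spec: FixtureSpec, target_id: str, group_id: str, max_nodes: int = 100
) -> tuple[list[DecoyGraph], list[LabeledDecoy], ComplexStructure]:
    """One synthetic target: native, MSA profile, and a balanced decoy set.

    Half the decoys are correct (rigid jitter at LRMSD 0.5-3.5 Å, native
    contact pattern preserved); half are incorrect (opposite receptor
    face, LRMSD >= 8 Å).
    """
    rng = np.random.default_rng(spec.seed)
    native = make_toy_complex(spec, complex_id=target_id)
    # binding-face columns are conserved, the rest variable — interfaces
    # carry an evolutionary fingerprint the profile features can expose
    face = binding_face_mask(len(native.receptor))
    rates = np.where(face, 0.08, 0.55)
    msa = make_toy_msa(
        native.receptor_sequence(), spec.msa_depth, rates, spec.seed + 1
    )
    profile = compute_profile(msa)

    n_correct = spec.n_decoys // 2
    n_wrong = spec.n_decoys - n_correct
    correct = []
    for k in range(n_correct):
        target = rng.uniform(0.5, 3.0)
        # resample until the decoy keeps a native-like contact patch
        for attempt in range(30):
            decoy, lrmsd = make_decoy_set(
                native, [target], seed=spec.seed + 2 + 1000 * attempt + k, mode="mixed"
            )[0]
            if len(_contact_pairs(decoy, 4.5)) >= 2:
                break
        decoy.id = f"{target_id}_d{k:04d}"
        correct.append((decoy, lrmsd))
    wrong = []
    for k in range(n_wrong):
        decoy, lrmsd = make_opposite_face_decoy(
            native, seed=spec.seed + 3 + k, decoy_id=f"{target_id}_w{k:04d}"
        )
        if lrmsd < 8.0:  # jitter brought it too close; push straight out
            decoy, lrmsd = make_decoy_set(
                native, [12.0], seed=spec.seed + 500 + k, mode="translation"
            )[0]
            decoy.id = f"{target_id}_w{k:04d}"
        wrong.append((decoy, lrmsd))

    graphs, labels = [], []
    for decoy, lrmsd in correct + wrong:
        g = featurize_decoy(decoy, profile, max_nodes=max_nodes, lrmsd=lrmsd)
        g.decoy_id = decoy.id
        graphs.append(g)
        labels.append(
            LabeledDecoy(
                graph_ref=decoy.id, target_id=target_id, group_id=group_id, lrmsd=lrmsd
            )
        )
    return graphs, labels, native


def make_planted_dataset(
    n_targets: int,
    decoys_per_target: int,
    seed: int,
    receptor_len: int = 55,
    peptide_len: int = 8,
    max_nodes: int = 100,
    targets_per_group: int = 2,
) -> PlantedDataset:
    """A multi-target planted-signal benchmark (class-balanced by construction)."""
    if n_targets < 1 or decoys_per_target < 2:
        raise ValueError("need at least one target and two decoys per target")
    graphs, labels, natives = [], [], {}
    for t in range(n_targets):
        spec = FixtureSpec(
            receptor_len=receptor_len + (t % 3) * 2,
            peptide_len=peptide_len + (t % 2),
            n_decoys=decoys_per_target,
            seed=(seed + 7919 * t) % (2**31 - 1),
        )
        tid = f"target_{t:03d}"
        gid = f"group_{t // max(targets_per_group, 1):03d}"
        g, l, native = make_planted_target(spec, tid, gid, max_nodes=max_nodes)
        graphs.extend(g)
        labels.extend(l)
        natives[tid] = native
    return PlantedDataset(graphs=graphs, labels=labels, natives=natives)


# ---------------------------------------------------------------------------
# on-disk mini-benchmark


def write_benchmark(
    out_dir,
    n_targets: int = 3,
    decoys_per_target: int = 20,
    seed: int = 0,
    receptor_len: int = 55,
    peptide_len: int = 8,
) -> Path:
    """Write a complete mini-benchmark directory of standard-format files.

    Layout: per target a native PDB, a FASTA alignment for the receptor
    and one PDB per decoy; plus ``targets.tsv`` and ``labels.tsv``
    manifests at the root.  Deterministic under ``seed``.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target_rows, label_rows = [], []
    for t in range(n_targets):
        tid = f"target_{t:03d}"
        tdir = out_dir / tid
        (tdir / "decoys").mkdir(parents=True, exist_ok=True)
        spec = FixtureSpec(
            receptor_len=receptor_len,
            peptide_len=peptide_len,
            n_decoys=decoys_per_target,
            seed=(seed + 7919 * t) % (2**31 - 1),
        )
        native = make_toy_complex(spec, complex_id=tid)
        write_pdb(native, tdir / "native.pdb")
        msa = make_toy_msa(
            native.receptor_sequence(), spec.msa_depth, spec.mutation_rate,
            spec.seed + 1,
        )
        with open(tdir / "msa.fasta", "w") as fh:
            for i, row in enumerate(msa.rows):
                fh.write(f">seq{i}\n{row}\n")

        rng = np.random.default_rng(spec.seed + 2)
        n_correct = decoys_per_target // 2
        targets_a = rng.uniform(0.5, 3.5, size=n_correct)
        decoys = make_decoy_set(native, targets_a, seed=spec.seed + 3, mode="mixed")
        for k in range(decoys_per_target - n_correct):
            decoys.append(
                make_opposite_face_decoy(
                    native, seed=spec.seed + 4 + k, decoy_id=f"{tid}_w{k:04d}"
                )
            )
        for decoy, lrmsd in decoys:
            path = tdir / "decoys" / f"{decoy.id}.pdb"
            write_pdb(decoy, path)
            label_rows.append(
                {
                    "decoy_id": decoy.id,
                    "target_id": tid,
                    "group_id": f"group_{t:03d}",
                    "path": str(path.relative_to(out_dir)),
                    "lrmsd": lrmsd,
                }
            )
        target_rows.append(
            {
                "target_id": tid,
                "native_pdb": f"{tid}/native.pdb",
                "msa": f"{tid}/msa.fasta",
                "receptor_chain": "A",
                "peptide_chain": "B",
            }
        )
    pd.DataFrame(target_rows).to_csv(out_dir / "targets.tsv", sep="\t", index=False)
    pd.DataFrame(label_rows).to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    return out_dir
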