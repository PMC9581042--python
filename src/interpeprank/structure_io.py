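"""Complex structure I/O and decoy-vs-native quality measures.

Reads receptor+peptide complexes from PDB files and computes the standard
docking model-quality measures: ligand RMSD (LRMSD), interface RMSD (iRMSD),
fraction of native contacts (fnat), the composite DockQ score and the CAPRI
quality class.  A decoy is "correct" if its LRMSD to the native pose is
below 4.0 Å — the resolution from which all-atom refinement can reliably
reach sub-ångström accuracy.

Conventions (documented, configurable where noted):

* LRMSD: superpose decoy receptor onto native receptor over backbone atoms
  (N, CA, C, O), then RMSD over peptide backbone atoms without refitting.
* iRMSD: native interface residues are those with any heavy atom within
  10.0 Å of the other chain in the native; backbone RMSD over those
  residues after superposing on them.
* fnat: native residue-residue contacts at 5.0 Å heavy-atom distance;
  fraction of those pairs reproduced in the decoy.
* DockQ: three-term average with scaling constants d1 = 8.5 Å (LRMSD) and
  d2 = 1.5 Å (iRMSD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: LRMSD below which a rigid-body decoy counts as correct (Å).
CORRECT_LRMSD_CUTOFF = 4.0

#: Heavy-atom distance defining a native residue-residue contact for fnat (Å).
FNAT_CONTACT_CUTOFF = 5.0

#: Heavy-atom distance defining the native interface for iRMSD (Å).
INTERFACE_CUTOFF = 10.0

#: DockQ distance scaling constants (Å).
DOCKQ_D1 = 8.5
DOCKQ_D2 = 1.5

CAPRI_CLASSES = ("Incorrect", "Acceptable", "Medium", "High")


@dataclass
class ResidueRecord:
    """One residue: identity plus its heavy-atom coordinates (Å)."""

    chain_id: str
    res_seq: int
    icode: str
    aa3: str
    aa1: str
    heavy_atoms: list[tuple[str, float, float, float]]

    def __post_init__(self):
        if not self.heavy_atoms:
            raise ValueError(
                f"residue {self.chain_id}{self.res_seq}{self.icode} has no heavy atoms"
            )
        coords = np.asarray([a[1:] for a in self.heavy_atoms], dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError(
                f"non-finite coordinates in residue {self.chain_id}{self.res_seq}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    def coords(self) -> np.ndarray:
        """Heavy-atom coordinates as an (n_atoms, 3) array."""
        return np.asarray([a[1:] for a in self.heavy_atoms], dtype=float)

    def backbone_coords(self, atoms=BACKBONE_ATOMS) -> dict[str, np.ndarray]:
        """Mapping atom name -> coordinate for the backbone atoms present."""
        have = {a[0]: np.asarray(a[1:], dtype=float) for a in self.heavy_atoms}
        return {name: have[name] for name in atoms if name in have}


@dataclass
class ComplexStructure:
    """A receptor+peptide complex at residue resolution."""

    receptor: list[ResidueRecord]
    peptide: list[ResidueRecord]
    id: str = ""

    def __post_init__(self):
        if len(self.peptide) < 1:
            raise ValueError(f"{self.id}: peptide has zero residues")
        if len(self.receptor) < 1:
            raise ValueError(f"{self.id}: receptor has zero residues")
        if len(self.peptide) > 25:
            warnings.warn(
                f"{self.id}: peptide has {len(self.peptide)} residues (> 25)",
                stacklevel=2,
            )
        if len(self.receptor) < 50:
            warnings.warn(
                f"{self.id}: receptor has {len(self.receptor)} residues (< 50)",
                stacklevel=2,
            )

    @property
    def residues(self) -> list[ResidueRecord]:
        """Peptide residues first (chain order), then receptor residues."""
        return list(self.peptide) + list(self.receptor)

    def peptide_sequence(self) -> str:
        return "".join(r.aa1 for r in self.peptide)

    def receptor_sequence(self) -> str:
        return "".join(r.aa1 for r in self.receptor)


@dataclass
class QualityMeasures:
    """Decoy-vs-native quality: LRMSD/iRMSD in Å, fnat and DockQ in [0,1]."""

    lrmsd: float
    irmsd: float
    fnat: float
    dockq: float = field(default=None)  # type: ignore[assignment]
    capri_class: str = field(default=None)  # type: ignore[assignment]
    is_correct: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.lrmsd < 0 or self.irmsd < 0:
            raise ValueError("RMSD values must be non-negative")
        if not 0.0 <= self.fnat <= 1.0:
            raise ValueError(f"fnat must be in [0,1], got {self.fnat}")
        if self.dockq is None:
            self.dockq = compute_dockq(self.lrmsd, self.irmsd, self.fnat)
        if self.capri_class is None:
            self.capri_class = classify_capri(self.lrmsd, self.irmsd, self.fnat)
        if self.is_correct is None:
            self.is_correct = bool(self.lrmsd < CORRECT_LRMSD_CUTOFF)


def _residue_from_biopdb(residue, chain_id: str) -> ResidueRecord | None:
    heavy = []
    for atom in residue.get_atoms():
        # DisorderedAtom yields its highest-occupancy conformer by default
        if atom.element == "H" or atom.get_name().startswith("H"):
            continue
        x, y, z = atom.get_coord()
        heavy.append((atom.get_name(), float(x), float(y), float(z)))
    if not heavy:
        return None
    aa3 = residue.get_resname().strip()
    aa1 = protein_letters_3to1.get(aa3, "X")
    _, res_seq, icode = residue.get_id()
    return ResidueRecord(
        chain_id=chain_id,
        res_seq=int(res_seq),
        icode=icode.strip(),
        aa3=aa3,
        aa1=aa1,
        heavy_atoms=heavy,
    )


def read_pdb(
    path,
    receptor_chains,
    peptide_chain: str,
    model_index: int = 0,
    structure_id: str | None = None,
) -> ComplexStructure:
    """Read a receptor+peptide complex from a PDB file.

    Parameters
    ----------
    path : str or Path
        PDB file with ATOM records.  If the file holds several MODEL blocks
        (separate decoys), ``model_index`` selects one.
    receptor_chains : str or iterable of str
        Chain identifier(s) of the receptor.
    peptide_chain : str
        Chain identifier of the peptide.

    Notes
    -----
    HETATM residues are excluded; alternate locations keep the
    highest-occupancy conformer; unknown residues map to one-letter code X.
    """
    if isinstance(receptor_chains, str):
        receptor_chains = [receptor_chains]
    receptor_chains = list(receptor_chains)

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(structure_id or "complex", str(path))
    models = list(structure.get_models())
    if model_index >= len(models):
        raise ValueError(f"{path}: model {model_index} not present ({len(models)} models)")
    model = models[model_index]

    chain_map = {chain.id: chain for chain in model.get_chains()}
    for cid in receptor_chains + [peptide_chain]:
        if cid not in chain_map:
            raise ValueError(f"{path}: chain '{cid}' not found (have {sorted(chain_map)})")

    def collect(chain_ids):
        out = []
        for cid in chain_ids:
            for residue in chain_map[cid].get_residues():
                hetflag = residue.get_id()[0]
                if hetflag.strip():  # HETATM / water
                    continue
                rec = _residue_from_biopdb(residue, cid)
                if rec is not None:
                    out.append(rec)
        return out

    receptor = collect(receptor_chains)
    peptide = collect([peptide_chain])
    if not peptide:
        raise ValueError(f"{path}: peptide chain '{peptide_chain}' has zero residues")
    sid = structure_id or str(path)
    return ComplexStructure(receptor=receptor, peptide=peptide, id=sid)


def count_models(path) -> int:
    """Number of MODEL blocks in a PDB file (1 if none)."""
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("c", str(path))
    return len(list(structure.get_models()))


def write_pdb(complex_: ComplexStructure, path) -> None:
    """Write a complex as a minimal PDB file (receptor chains, then peptide)."""
    serial = 1
    lines = []
    for res in complex_.receptor + complex_.peptide:
        for name, x, y, z in res.heavy_atoms:
            element = name[0]
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{res.aa3:>3s} {res.chain_id}"
                f"{res.res_seq:4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{element:>2s}"
            )
            serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# superposition and RMSD


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid-body superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation)`` such that ``mobile @ rotation.T +
    translation`` minimizes the RMSD to ``target`` (SVD solution, with the
    usual determinant correction to exclude reflections).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD of ``mobile`` vs ``target`` after optimal superposition."""
    rot, trans = kabsch(mobile, target)
    return rmsd(mobile @ rot.T + trans, target)


def _check_match(decoy: ComplexStructure, native: ComplexStructure) -> None:
    for name, d_res, n_res in (
        ("receptor", decoy.receptor, native.receptor),
        ("peptide", decoy.peptide, native.peptide),
    ):
        if len(d_res) != len(n_res):
            raise ValueError(
                f"{name} length mismatch: decoy {len(d_res)} vs native {len(n_res)}"
            )
        for d, n in zip(d_res, n_res):
            if d.key != n.key or d.aa1 != n.aa1:
                raise ValueError(
                    f"{name} residue mismatch at decoy {d.key}/{d.aa1} "
                    f"vs native {n.key}/{n.aa1}"
                )


def _paired_backbone(
    decoy_res: list[ResidueRecord],
    native_res: list[ResidueRecord],
    min_residues: int = 3,
):
    """Matched backbone coordinate arrays over residues with complete pairs."""
    d_pts, n_pts = [], []
    kept = 0
    for d, n in zip(decoy_res, native_res):
        db = d.backbone_coords()
        nb = n.backbone_coords()
        common = [a for a in BACKBONE_ATOMS if a in db and a in nb]
        if len(common) < len(BACKBONE_ATOMS):
            logger.warning("residue %s missing backbone atoms; using %s", d.key, common)
        if not common:
            continue
        kept += 1
        for a in common:
            d_pts.append(db[a])
            n_pts.append(nb[a])
    if kept < min_residues:
        raise ValueError(
            f"only {kept} residues with backbone atoms (need >= {min_residues})"
        )
    return np.asarray(d_pts), np.asarray(n_pts)


def compute_lrmsd(decoy: ComplexStructure, native: ComplexStructure) -> float:
    """Ligand RMSD: peptide backbone RMSD after receptor superposition (Å)."""
    _check_match(decoy, native)
    d_rec, n_rec = _paired_backbone(decoy.receptor, native.receptor)
    rot, trans = kabsch(d_rec, n_rec)
    d_pep, n_pep = _paired_backbone(decoy.peptide, native.peptide)
    return rmsd(d_pep @ rot.T + trans, n_pep)


def _contact_pairs(complex_: ComplexStructure, cutoff: float) -> set:
    """Receptor-peptide residue pairs with any heavy atoms within ``cutoff``."""
    pairs = set()
    pep_coords = [r.coords() for r in complex_.peptide]
    for i, rec in enumerate(complex_.receptor):
        rc = rec.coords()
        for j, pc in enumerate(pep_coords):
            d2 = np.sum((rc[:, None, :] - pc[None, :, :]) ** 2, axis=-1)
            if np.min(d2) <= cutoff**2:
                pairs.add((i, j))
    return pairs


def native_interface_residues(
    native: ComplexStructure, cutoff: float = INTERFACE_CUTOFF
):
    """Indices of native interface residues: (receptor idx list, peptide idx list)."""
    pairs = _contact_pairs(native, cutoff)
    rec_idx = sorted({i for i, _ in pairs})
    pep_idx = sorted({j for _, j in pairs})
    return rec_idx, pep_idx


def compute_irmsd(
    decoy: ComplexStructure,
    native: ComplexStructure,
    interface_cutoff: float = INTERFACE_CUTOFF,
) -> float:
    """Interface RMSD: backbone RMSD over native-interface residues (Å)."""
    _check_match(decoy, native)
    rec_idx, pep_idx = native_interface_residues(native, interface_cutoff)
    if not rec_idx:
        raise ValueError(f"{native.id}: native has no interface contacts (degenerate)")
    d_res = [decoy.receptor[i] for i in rec_idx] + [decoy.peptide[j] for j in pep_idx]
    n_res = [native.receptor[i] for i in rec_idx] + [native.peptide[j] for j in pep_idx]
    d_pts, n_pts = _paired_backbone(d_res, n_res, min_residues=2)
    return superposed_rmsd(d_pts, n_pts)


def compute_fnat(
    decoy: ComplexStructure,
    native: ComplexStructure,
    contact_cutoff: float = FNAT_CONTACT_CUTOFF,
) -> float:
    """Fraction of native receptor-peptide residue contacts recalled by the decoy."""
    _check_match(decoy, native)
    native_pairs = _contact_pairs(native, contact_cutoff)
    if not native_pairs:
        raise ValueError(f"{native.id}: native has no contacts (degenerate)")
    decoy_pairs = _contact_pairs(decoy, contact_cutoff)
    return len(native_pairs & decoy_pairs) / len(native_pairs)


def classify_capri(lrmsd: float, irmsd: float, fnat: float) -> str:
    """CAPRI quality class from (LRMSD, iRMSD, fnat).

    High:       LRMSD < 1.0 and iRMSD < 0.5 and fnat > 0.8
    Medium:     LRMSD < 2.0 and iRMSD < 1.0 and fnat > 0.5
    Acceptable: LRMSD < 5.0 and iRMSD < 2.0 and fnat > 0.2
    otherwise Incorrect.  Higher classes imply the lower ones.
    """
    if lrmsd < 1.0 and irmsd < 0.5 and fnat > 0.8:
        return "High"
    if lrmsd < 2.0 and irmsd < 1.0 and fnat > 0.5:
        return "Medium"
    if lrmsd < 5.0 and irmsd < 2.0 and fnat > 0.2:
        return "Acceptable"
    return "Incorrect"


def compute_dockq(lrmsd: float, irmsd: float, fnat: float) -> float:
    """DockQ composite score: mean of fnat and scaled LRMSD/iRMSD terms."""
    if lrmsd < 0 or irmsd < 0 or fnat < 0:
        raise ValueError("DockQ inputs must be non-negative")
    lr = 1.0 / (1.0 + (lrmsd / DOCKQ_D1) ** 2)
    ir = 1.0 / (1.0 + (irmsd / DOCKQ_D2) ** 2)
    return (fnat + lr + ir) / 3.0


def evaluate_decoy(decoy: ComplexStructure, native: ComplexStructure) -> QualityMeasures:
    """All quality measures of a decoy against its native complex."""
    lrmsd = compute_lrmsd(decoy, native)
    irmsd = compute_irmsd(decoy, native)
    fnat = compute_fnat(decoy, native)
    return QualityMeasures(lrmsd=lrmsd, irmsd=irmsd, fnat=fnat)


def quality_table(measures: dict[str, QualityMeasures]):
    """Quality measures as a pandas DataFrame (id-indexed), TSV-ready."""
    import pandas as pd

    rows = [
        {
            "id": did,
            "lrmsd": q.lrmsd,
            "irmsd": q.irmsd,
            "fnat": q.fnat,
            "dockq": q.dockq,
            "capri_class": q.capri_class,
            "is_correct": q.is_correct,
        }
        for did, q in measures.items()
    ]
    return pd.DataFrame(rows)
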