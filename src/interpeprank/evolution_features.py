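"""Per-residue evolutionary node features from a multiple sequence alignment.

Two profile features are computed per alignment column, each 21 values wide
(20 amino acids + gap):

* PSSM:          ``PSSM_i = -log(p_i / p_bi)``
* self-entropy:  ``S_i    = -p_i * log(p_i / p_bi)``

where ``p_i`` is the observed frequency of a symbol in column *i* (with a
background-distributed pseudocount) and ``p_bi`` the background probability
of that symbol.  The algebraic identity ``S = p * PSSM`` holds elementwise.

The one-hot amino-acid encoding uses a different 21-letter alphabet:
20 amino acids plus X for unknown residues.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: Profile alphabet: 20 amino acids + gap.
PROFILE_ALPHABET = AA20 + GAP
#: One-hot alphabet: 20 amino acids + X (unknown).
ONEHOT_ALPHABET = AA20 + "X"

_PROFILE_INDEX = {c: i for i, c in enumerate(PROFILE_ALPHABET)}
_ONEHOT_INDEX = {c: i for i, c in enumerate(ONEHOT_ALPHABET)}

# BLOSUM62 amino-acid background frequencies (Henikoff & Henikoff marginals),
# keyed in AA20 order.  Renormalized below to leave room for the gap symbol.
_BLOSUM62_BG = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

#: Background probability assigned to the gap symbol.
GAP_BACKGROUND = 0.05


def background_frequencies(gap_background: float = GAP_BACKGROUND) -> np.ndarray:
    """Background distribution over the 21-symbol profile alphabet.

    The 20 amino-acid backgrounds follow BLOSUM62 marginals, renormalized to
    ``1 - gap_background``; the gap symbol gets ``gap_background``.
    """
    aa = np.array([_BLOSUM62_BG[c] for c in AA20], dtype=float)
    aa = aa / aa.sum() * (1.0 - gap_background)
    return np.concatenate([aa, [gap_background]])


@dataclass
class MultipleSequenceAlignment:
    """An alignment in query-column space (first row = ungapped query)."""

    query: str
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment has no rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        first = self.rows[0].replace(GAP, "")
        if first != self.query:
            raise ValueError("first alignment row does not reproduce the query")
        alphabet = set(PROFILE_ALPHABET) | {"X"}
        bad = set("".join(self.rows)) - alphabet
        if bad:
            raise ValueError(f"unexpected alignment symbols: {sorted(bad)}")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])


def _read_fasta_rows(path) -> list[str]:
    rows, current = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current:
                    rows.append("".join(current))
                    current = []
            else:
                current.append(line)
    if current:
        rows.append("".join(current))
    return rows


def read_msa(path, format: str | None = None) -> MultipleSequenceAlignment:
    """Read an alignment from FASTA or A3M.

    A3M lowercase letters mark insertions relative to the query and are
    removed, leaving all rows in query-column space.  The format is guessed
    from the file suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unknown MSA format '{format}'")
    raw = _read_fasta_rows(path)
    if not raw:
        raise ValueError(f"{path}: empty alignment")
    if format == "a3m":
        rows = ["".join(c for c in row if not c.islower()) for row in raw]
    else:
        rows = [row.upper() for row in raw]
    rows = [r.replace(".", GAP).upper() for r in rows]
    query = rows[0].replace(GAP, "")
    return MultipleSequenceAlignment(query=query, rows=rows)


def column_frequencies(
    msa: MultipleSequenceAlignment,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Observed symbol frequencies per column, shape (length, 21).

    Counts over the 20 amino acids + gap; X is treated as unobserved and
    excluded.  A total pseudocount weight is distributed according to the
    background so every probability is strictly positive:

        p = (count + pseudocount * p_b) / (n_observed + pseudocount)

    Each column sums to 1.
    """
    if background is None:
        background = background_frequencies()
    counts = np.zeros((msa.length, 21), dtype=float)
    observed = np.zeros(msa.length, dtype=float)
    for row in msa.rows:
        for i, c in enumerate(row):
            idx = _PROFILE_INDEX.get(c)
            if idx is not None:
                counts[i, idx] += 1.0
                observed[i] += 1.0
    denom = observed + pseudocount
    if np.any(denom <= 0):
        raise ValueError("column with no observations and zero pseudocount")
    return (counts + pseudocount * background) / denom[:, None]


def pssm(p: np.ndarray, background: np.ndarray | None = None, base: str = "e") -> np.ndarray:
    """Position-specific scoring matrix: ``-log(p / p_b)`` per column symbol."""
    if background is None:
        background = background_frequencies()
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(background <= 0):
        raise ValueError("probabilities must be strictly positive (use pseudocounts)")
    ratio = np.log(p / background)
    if base == "2":
        ratio = ratio / np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    return -ratio


def self_entropy(
    p: np.ndarray, background: np.ndarray | None = None, base: str = "e"
) -> np.ndarray:
    """Self-entropy: ``-p * log(p / p_b)``, the frequency-weighted PSSM."""
    p = np.asarray(p, dtype=float)
    return p * pssm(p, background, base)


def one_hot(aa1: str) -> np.ndarray:
    """One-hot encode a one-letter residue code over 20 amino acids + X."""
    idx = _ONEHOT_INDEX.get(aa1)
    if idx is None:
        raise ValueError(f"unknown residue letter '{aa1}'")
    v = np.zeros(21, dtype=float)
    v[idx] = 1.0
    return v


@dataclass
class ProfileFeatures:
    """PSSM and self-entropy profiles for a query sequence."""

    query: str
    pssm: np.ndarray          # (L, 21)
    self_entropy: np.ndarray  # (L, 21)
    p: np.ndarray             # (L, 21) observed frequencies with pseudocounts
    background: np.ndarray    # (21,)

    def __post_init__(self):
        L = len(self.query)
        for name in ("pssm", "self_entropy", "p"):
            arr = getattr(self, name)
            if arr.shape != (L, 21):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({L}, 21)")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")


def compute_profile(
    msa: MultipleSequenceAlignment,
    pseudocount: float = 1.0,
    gap_background: float = GAP_BACKGROUND,
    base: str = "e",
) -> ProfileFeatures:
    """PSSM + self-entropy profile of an alignment's query sequence."""
    bg = background_frequencies(gap_background)
    p = column_frequencies(msa, pseudocount=pseudocount, background=bg)
    return ProfileFeatures(
        query=msa.query,
        pssm=pssm(p, bg, base),
        self_entropy=self_entropy(p, bg, base),
        p=p,
        background=bg,
    )


def write_profile_tsv(profile: ProfileFeatures, path) -> None:
    """Write a profile as TSV: position, residue, 21 PSSM + 21 entropy columns."""
    import pandas as pd

    cols = {}
    cols["position"] = np.arange(len(profile.query))
    cols["residue"] = list(profile.query)
    for j, c in enumerate(PROFILE_ALPHABET):
        cols[f"pssm_{c if c != GAP else 'gap'}"] = profile.pssm[:, j]
    for j, c in enumerate(PROFILE_ALPHABET):
        cols[f"entropy_{c if c != GAP else 'gap'}"] = profile.self_entropy[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path) -> tuple[str, np.ndarray, np.ndarray]:
    """Read a profile TSV; returns (query, pssm, self_entropy)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    query = "".join(df["residue"])
    pssm_cols = [c for c in df.columns if c.startswith("pssm_")]
    ent_cols = [c for c in df.columns if c.startswith("entropy_")]
    return query, df[pssm_cols].to_numpy(), df[ent_cols].to_numpy()
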