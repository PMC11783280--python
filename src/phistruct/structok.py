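"""Structure-aware tokenization.

A structure-aware protein language model consumes, for a protein of length n,
the token sequence ((r_1, f_1), ..., (r_n, f_n)) where r_i is the amino-acid
residue and f_i is a letter from a 20-letter structure alphabet describing the
residue's tertiary interaction environment (the 3Di alphabet).  Each residue
also carries a pLDDT confidence score in [0, 100] from the structure
predictor, conventionally stored in the B-factor column of the PDB file.

This module pairs the three channels into one object, applies masking
strategies (mask all residues, mask all structure letters, or mask structure
letters only where the predicted structure is low-confidence), and parses the
residue/pLDDT channels out of predicted-structure PDB files.  The structure
alphabet is treated as opaque: deriving it from 3D coordinates is a structure
search tool's job, not ours.
"""

from __future__ import annotations

import enum
import io
import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.SeqUtils import seq1

from .errors import EmptyStructureError, FormatError

__all__ = [
    "MASK_TOKEN",
    "MaskKind",
    "MaskStrategy",
    "StructureAwareSequence",
    "apply_mask",
    "mean_plddt",
    "pair_tokens",
    "parse_predicted_structure",
]

logger = logging.getLogger(__name__)

MASK_TOKEN = "#"
AMINO_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ALPHABET = frozenset(AMINO_LETTERS + "X" + MASK_TOKEN)
# 20-letter lowercase structure alphabet (3Di-style), plus the mask sentinel
STRUCTURE_LETTERS = AMINO_LETTERS.lower()
STRUCTURE_ALPHABET = frozenset(STRUCTURE_LETTERS + MASK_TOKEN)


@dataclass(frozen=True)
class StructureAwareSequence:
    """Paired residue/structure tokens with per-residue confidence."""

    residues: str
    structure_letters: str
    plddt: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n == 0:
            raise ValueError("empty sequence")
        if len(self.structure_letters) != n or len(self.plddt) != n:
            raise ValueError(
                "length mismatch: residues={} structure={} plddt={}".format(
                    n, len(self.structure_letters), len(self.plddt)
                )
            )
        for i, ch in enumerate(self.residues):
            if ch not in AMINO_ALPHABET:
                raise ValueError(f"invalid residue {ch!r} at position {i}")
        for i, ch in enumerate(self.structure_letters):
            if ch not in STRUCTURE_ALPHABET:
                raise ValueError(f"invalid structure letter {ch!r} at position {i}")
        for i, v in enumerate(self.plddt):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"pLDDT {v} out of [0, 100] at position {i}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def tokens(self) -> list[tuple[str, str]]:
        """The (r_i, f_i) pairs."""
        return list(zip(self.residues, self.structure_letters))

    def interleaved(self) -> str:
        """r1 f1 r2 f2 ... as one string (the common on-disk token layout)."""
        return "".join(r + f for r, f in self.tokens)

    def masked_fraction(self) -> float:
        masked = sum(
            1
            for r, f in zip(self.residues, self.structure_letters)
            if r == MASK_TOKEN or f == MASK_TOKEN
        )
        return masked / len(self)


class MaskKind(enum.Enum):
    NONE = "none"
    MASK_RESIDUE = "residue"
    MASK_STRUCTURE = "structure"
    MASK_LOWCONF_STRUCTURE = "lowconf"


@dataclass(frozen=True)
class MaskStrategy:
    """Which token channel to mask; threshold applies to LOWCONF only.

    A pLDDT strictly below ``plddt_threshold`` marks a residue's structure
    letter as low-confidence.
    """

    kind: MaskKind = MaskKind.NONE
    plddt_threshold: float = 70.0


def pair_tokens(
    residues: str, structure_letters: str, plddt
) -> StructureAwareSequence:
    """Pair the residue, structure and confidence channels.

    pLDDT values on a 0-1 scale (all values <= 1) are auto-rescaled to 0-100
    with a logged notice.
    """
    if len(residues) != len(structure_letters):
        raise ValueError(
            f"length mismatch: residues={len(residues)} "
            f"structure={len(structure_letters)}"
        )
    vals = tuple(float(v) for v in plddt)
    if vals and max(vals) <= 1.0:
        logger.info("pLDDT values all <= 1; rescaling from 0-1 to 0-100")
        vals = tuple(v * 100.0 for v in vals)
    return StructureAwareSequence(residues, structure_letters, vals)


def apply_mask(
    seq: StructureAwareSequence, strategy: MaskStrategy
) -> StructureAwareSequence:
    """Return a copy of ``seq`` with the strategy's channel masked by '#'."""
    if strategy.kind is MaskKind.NONE:
        return seq
    if strategy.kind is MaskKind.MASK_RESIDUE:
        return replace(seq, residues=MASK_TOKEN * len(seq))
    if strategy.kind is MaskKind.MASK_STRUCTURE:
        return replace(seq, structure_letters=MASK_TOKEN * len(seq))
    if strategy.kind is MaskKind.MASK_LOWCONF_STRUCTURE:
        letters = "".join(
            MASK_TOKEN if p < strategy.plddt_threshold else f
            for f, p in zip(seq.structure_letters, seq.plddt)
        )
        return replace(seq, structure_letters=letters)
    raise ValueError(f"unknown mask kind {strategy.kind!r}")


def mean_plddt(plddt) -> float:
    """Per-protein confidence: arithmetic mean of per-residue pLDDT."""
    arr = np.asarray(list(plddt), dtype=float)
    if arr.size == 0:
        raise ValueError("empty pLDDT list")
    return float(arr.mean())


def parse_predicted_structure(pdb_text: str) -> tuple[str, list[float]]:
    """Extract the residue string and per-residue pLDDT from PDB text.

    Predicted-structure PDB files store the per-residue pLDDT in the B-factor
    column; we read it off the CA atom of each residue, in residue order.
    Unknown residue names map to 'X' with a warning; for altloc duplicates the
    parser's selected conformer is used and a warning is logged.
    """
    if not pdb_text.strip():
        raise EmptyStructureError("empty PDB text")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("pred", io.StringIO(pdb_text))
    except Exception as exc:
        raise FormatError(f"unparseable PDB text: {exc}") from exc
    residues: list[str] = []
    plddt: list[float] = []
    for model in structure:
        for chain in model:
            for res in chain:
                if "CA" not in res:
                    continue
                atom = res["CA"]
                if atom.is_disordered():
                    logger.warning(
                        "altloc CA in residue %s; keeping selected conformer",
                        res.get_id(),
                    )
                one = seq1(res.get_resname(), undef_code="X")
                if one == "X" and res.get_resname() not in ("UNK", "XAA"):
                    logger.warning(
                        "unknown residue name %r mapped to 'X'", res.get_resname()
                    )
                residues.append(one)
                plddt.append(float(atom.get_bfactor()))
        break  # first model only
    if not residues:
        raise EmptyStructureError("no CA atoms found in PDB text")
    return "".join(residues), plddt
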