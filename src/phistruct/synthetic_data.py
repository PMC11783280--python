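"""Synthetic phage-protein fixtures with the statistical structure the
pipeline assumes.

Real inputs to this pipeline — annotated receptor-binding proteins,
predicted structures with per-residue confidence, and language-model
embeddings — all come from external resources.  This module generates
download-free stand-ins that reproduce the *statistics* the pipeline relies
on, so every stage can be exercised and tested end to end:

* sequence families grown from random ancestors by seeded point mutations,
  so pairwise identity within a family spans the clustering thresholds
  (roughly 0.45-1.0 at the default divergence) while identity across
  families sits at the ~0.13 background of unrelated sequences;
* per-protein confidence profiles: protein-level mean pLDDT drawn from a
  clipped normal centered near 80 (the typical predicted-structure range for
  these proteins), per-residue values scattered around it;
* a 3Di-style structure string per protein and a toy CA-only PDB file whose
  B-factor column round-trips through the structure parser;
* genus-conditional clustered embeddings via the synthetic embedder, plus an
  out-of-scope ("outgroup") class pool.

Everything is bit-reproducible per seed.  The sequences are not
biophysically meaningful; see the methods note for what that does and does
not imply about tests built on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.SeqUtils import seq3

from .embed import EmbeddedDataset, OUTGROUP_LABEL, SyntheticEmbedder
from .rbp_catalog import ProteinRecord
from .structok import (
    AMINO_LETTERS,
    STRUCTURE_LETTERS,
    StructureAwareSequence,
    pair_tokens,
)

__all__ = [
    "ESKAPEE_GENERA",
    "GeneratorConfig",
    "StructureChannel",
    "SyntheticDataset",
    "generate_full_dataset",
    "generate_sequences",
    "generate_structure_channel",
]

# the seven genera of interest, in the conventional reporting order
ESKAPEE_GENERA = (
    "Enterococcus",
    "Staphylococcus",
    "Klebsiella",
    "Acinetobacter",
    "Pseudomonas",
    "Enterobacter",
    "Escherichia",
)

_RBP_PRODUCTS = (
    "tail fiber protein",
    "tailspike protein",
    "receptor-binding protein",
    "putative tail fibre protein",
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dataset.

    n_per_genus : proteins per in-scope genus (int, or dict keyed by genus).
    n_outgroup : proteins in the out-of-scope pool.
    families_per_genus : independent ancestor families per genus.
    subfamilies_per_family : divergent lineages within each family.
    embed_dim : embedding length L.
    center_separation / sigma : between-genus center distance and
        within-genus spread of the synthetic embeddings.
    family_divergence : substitution rate separating subfamily ancestors
        from the family ancestor; 0 makes all family members identical.
        Members scatter around their subfamily ancestor at rates up to
        family_divergence / 15, giving three well-separated identity bands
        (within subfamily ~0.95, across subfamilies ~0.5, across families
        ~0.13 at the default 0.3) that straddle the usual clustering
        thresholds without sitting on them.
    length_median / length_spread : protein length distribution (aa).
    plddt_mean / plddt_spread : distribution of per-protein mean pLDDT.
    residue_plddt_spread : per-residue scatter around the protein mean.
    """

    n_per_genus: int | dict = 10
    n_outgroup: int = 10
    families_per_genus: int = 2
    subfamilies_per_family: int = 2
    embed_dim: int = 1280
    center_separation: float = 10.0
    sigma: float = 1.0
    mask_sensitivity: float = 1.0
    family_divergence: float = 0.3
    length_median: int = 550
    length_spread: int = 100
    plddt_mean: float = 80.0
    plddt_spread: float = 5.0
    residue_plddt_spread: float = 8.0
    seed: int = 0

    def count_for(self, genus: str) -> int:
        if isinstance(self.n_per_genus, dict):
            return int(self.n_per_genus[genus])
        return int(self.n_per_genus)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_LETTERS))[rng.integers(0, 20, length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    letters = list(seq)
    hits = np.where(rng.random(len(letters)) < rate)[0]
    for i in hits:
        # substitute uniformly over the 19 alternatives
        choices = [a for a in AMINO_LETTERS if a != letters[i]]
        letters[i] = choices[rng.integers(0, 19)]
    return "".join(letters)


def _subfamily_ancestors(rng, base: str, n_sub: int, rate: float) -> list[str]:
    """Subfamily founders at a controlled identity to the family founder.

    Candidates are regenerated (seeded rejection sampling) until every
    founder pair sits in the mid identity band between the usual clustering
    thresholds, so greedy clustering sees coherent subfamilies rather than
    chains that straddle a threshold.
    """
    from .simsplit import pairwise_identity

    if rate == 0.0 or n_sub <= 1:
        return [base] * max(1, n_sub)
    # independent founders at rate r diverge pairwise to ~(1-r)^2 identity
    target = (1.0 - rate) ** 2 + 0.02
    lo, hi = target - 0.05, target + 0.05
    ancestors = [_mutate(rng, base, rate)]
    for _ in range(n_sub - 1):
        candidate = _mutate(rng, base, rate)
        for _ in range(80):
            if all(lo <= pairwise_identity(candidate, a) <= hi for a in ancestors):
                break
            candidate = _mutate(rng, base, rate)
        ancestors.append(candidate)
    return ancestors


def generate_sequences(config: GeneratorConfig) -> list[ProteinRecord]:
    """Two-level ancestor-mutation families for each genus plus the outgroup."""
    rng = np.random.default_rng(np.uint32(config.seed))
    member_div = config.family_divergence / 15.0
    records: list[ProteinRecord] = []
    groups = list(ESKAPEE_GENERA) + [OUTGROUP_LABEL]
    for genus in groups:
        n = config.n_outgroup if genus == OUTGROUP_LABEL else config.count_for(genus)
        if n <= 0:
            continue
        n_fam = max(1, min(config.families_per_genus, n))
        sizes = [n // n_fam + (1 if i < n % n_fam else 0) for i in range(n_fam)]
        for fam, size in enumerate(sizes):
            length = int(
                np.clip(
                    rng.normal(config.length_median, config.length_spread),
                    150, 2000,
                )
            )
            base = _random_sequence(rng, length)
            n_sub = max(1, min(config.subfamilies_per_family, size))
            ancestors = _subfamily_ancestors(
                rng, base, n_sub, config.family_divergence
            )
            seen: set[str] = set()
            for i in range(size):
                ancestor = ancestors[i % n_sub]
                rate = rng.uniform(0.1, 1.0) * member_div
                seq = _mutate(rng, ancestor, rate)
                if member_div > 0:
                    while seq in seen:  # the catalog is duplicate-free
                        pos = int(rng.integers(0, len(seq)))
                        alt = [a for a in AMINO_LETTERS if a != seq[pos]]
                        seq = seq[:pos] + alt[rng.integers(0, 19)] + seq[pos + 1:]
                    seen.add(seq)
                pid = f"{genus.lower()}_f{fam}_{i:03d}"
                records.append(
                    ProteinRecord(
                        id=pid,
                        phage_id=f"phage_{genus.lower()}_{fam}_{i:03d}",
                        product=_RBP_PRODUCTS[rng.integers(0, len(_RBP_PRODUCTS))],
                        sequence=seq,
                        host_genus=genus,
                    )
                )
    return records


def _toy_pdb(residues: str, plddt: list[float]) -> str:
    """CA-only PDB text with pLDDT in the B-factor column."""
    lines = []
    for i, (aa, b) in enumerate(zip(residues, plddt), start=1):
        resname = seq3(aa).upper()
        x, y, z = 1.5 * i, 0.3 * i, 0.1 * i  # geometry is a placeholder
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:>3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@dataclass
class StructureChannel:
    """Per-protein structure strings, confidence profiles and PDB texts."""

    sequences: dict[str, StructureAwareSequence]
    pdb_texts: dict[str, str]


def generate_structure_channel(
    records: list[ProteinRecord], config: GeneratorConfig
) -> StructureChannel:
    """3Di-style strings and pLDDT profiles for each record.

    pLDDT values are rounded to 2 decimals (the PDB B-factor precision) so
    the toy PDB files round-trip exactly through the structure parser.
    """
    rng = np.random.default_rng([np.uint32(config.seed), 1])
    letters = np.array(list(STRUCTURE_LETTERS))
    seqs: dict[str, StructureAwareSequence] = {}
    pdbs: dict[str, str] = {}
    for rec in records:
        n = len(rec.sequence)
        struct = "".join(letters[rng.integers(0, len(letters), n)])
        protein_mean = float(
            np.clip(rng.normal(config.plddt_mean, config.plddt_spread), 0, 100)
        )
        per_res = np.clip(
            rng.normal(protein_mean, config.residue_plddt_spread, n), 0, 100
        )
        per_res = np.round(per_res, 2)
        saseq = pair_tokens(rec.sequence, struct, per_res.tolist())
        seqs[rec.id] = saseq
        pdbs[rec.id] = _toy_pdb(rec.sequence, per_res.tolist())
    return StructureChannel(sequences=seqs, pdb_texts=pdbs)


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, in one bundle."""

    records: list[ProteinRecord]
    structures: StructureChannel
    embeddings: EmbeddedDataset
    config: GeneratorConfig = field(repr=False)


def generate_full_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Sequences + structure channel + genus-conditional embeddings."""
    records = generate_sequences(config)
    structures = generate_structure_channel(records, config)
    embedder = SyntheticEmbedder(
        classes=list(ESKAPEE_GENERA) + [OUTGROUP_LABEL],
        dim=config.embed_dim,
        center_separation=config.center_separation,
        sigma=config.sigma,
        mask_sensitivity=config.mask_sensitivity,
        seed=config.seed,
    ).fit()
    triples = [
        (rec.id, structures.sequences[rec.id], rec.host_genus) for rec in records
    ]
    embeddings = embedder.transform(triples)
    embeddings.provenance["generator"] = asdict(config)
    return SyntheticDataset(
        records=records, structures=structures, embeddings=embeddings, config=config
    )
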