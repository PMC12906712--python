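"""In-silico tryptic digestion and cross-proteome peptide uniqueness.

Used to decide whether an observed peptide (e.g. one from an
administered antibody of another species) could have come from the host
proteome: both proteomes are digested with the same rule and the
peptide is looked up in each index.  The default rule is Trypsin/P —
cleave after every K or R with *no* proline suppression — with one
missed cleavage, matching common DIA search settings.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_RESIDUES = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

UNIQUE_TO_A = "unique_to_a"
UNIQUE_TO_B = "unique_to_b"
SHARED = "shared"
ABSENT = "absent"


def cleave(sequence: str, max_missed: int = 1, trypsin_p: bool = True) -> set[str]:
    """Tryptic peptides of a sequence with up to ``max_missed`` missed cleavages.

    Trypsin/P cleaves after every K or R; with ``trypsin_p=False`` the
    classic rule suppresses cleavage before proline.
    """
    sequence = sequence.upper()
    if not _VALID_RESIDUES.match(sequence):
        raise ValueError("sequence contains non-amino-acid characters")
    cut_after = []
    for i, res in enumerate(sequence[:-1]):
        if res in "KR" and (trypsin_p or sequence[i + 1] != "P"):
            cut_after.append(i + 1)
    bounds = [0] + cut_after + [len(sequence)]
    fragments = [sequence[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: set[str] = set()
    for start in range(len(fragments)):
        for missed in range(0, max_missed + 1):
            end = start + missed + 1
            if end > len(fragments):
                break
            peptides.add("".join(fragments[start:end]))
    return peptides


def digest_fasta(
    fasta_path: str | Path,
    max_missed: int = 1,
    trypsin_p: bool = True,
    min_length: int = 6,
    max_length: int = 30,
    met_excision: bool = True,
) -> dict[str, set[str]]:
    """Digest a proteome FASTA into a peptide → accession-set index.

    With ``met_excision`` (default on, mirroring common search-engine
    settings) peptides from both the intact sequence and the
    N-terminal-methionine-excised form are indexed.  Entries with
    non-amino-acid characters are skipped with a warning.
    """
    index: dict[str, set[str]] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        header = rec.id
        if "|" in header:
            parts = header.split("|")
            accession = parts[1] if len(parts) > 1 and parts[1] else parts[0]
        else:
            accession = header
        seq = str(rec.seq).upper().rstrip("*")
        forms = [seq]
        if met_excision and seq.startswith("M") and len(seq) > 1:
            forms.append(seq[1:])
        peptides: set[str] = set()
        try:
            for form in forms:
                peptides |= cleave(form, max_missed=max_missed, trypsin_p=trypsin_p)
        except ValueError:
            logger.warning("skipping entry %s: non-amino-acid characters", accession)
            continue
        for pep in peptides:
            if min_length <= len(pep) <= max_length:
                index.setdefault(pep, set()).add(accession)
    return index


def peptide_uniqueness(
    peptide: str,
    index_a: dict[str, set[str]],
    index_b: dict[str, set[str]],
) -> str:
    """Classify a peptide's membership across two digest indexes.

    Returns one of ``unique_to_a``, ``unique_to_b``, ``shared``,
    ``absent``.  Both indexes must have been built with identical
    digest settings for the comparison to be meaningful.
    """
    peptide = peptide.upper()
    if not _VALID_RESIDUES.match(peptide):
        raise ValueError("peptide contains non-amino-acid characters")
    in_a, in_b = peptide in index_a, peptide in index_b
    if in_a and in_b:
        return SHARED
    if in_a:
        return UNIQUE_TO_A
    if in_b:
        return UNIQUE_TO_B
    return ABSENT
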