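"""Readers, writers and domain containers for the external formats.

Formats handled
---------------
* FASTA protein sequences (via :mod:`Bio.SeqIO`).
* PSI-BLAST ASCII PSSM files (the ``-out_ascii_pssm`` layout): the first 20
  score columns are extracted and remapped from PSI-BLAST column order to the
  canonical alphabetical amino-acid order.
* Tab-separated fingerprint tables: drug id followed by 256 numeric values.
* Tab-separated pair lists: drug id, protein id, optional label in {1, -1}.

Lines whose first non-blank character is ``#`` are treated as comments in the
tabular formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import (
    AA_INDEX,
    CANONICAL_ORDER,
    CANONICAL_TO_PSIBLAST,
    NON_STANDARD,
    PSIBLAST_ORDER,
    PSIBLAST_TO_CANONICAL,
)
from .errors import FormatError, UnknownIDError, ValidationError

N_FINGERPRINT = 256

#: Provenance of the evolutionary profiles this package expects: PSI-BLAST
#: against UniProtKB/Swiss-Prot, 3 iterations, E-value cutoff 0.001. The
#: search itself is delegated to the user (or replaced by synthetic profiles);
#: the parameters are recorded in dataset metadata for the record.
PSIBLAST_PROVENANCE = {
    "program": "psiblast",
    "iterations": 3,
    "evalue_cutoff": 0.001,
    "database": "UniProtKB/Swiss-Prot",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinSequence:
    """A protein identifier plus its residue string over the 20-letter alphabet.

    ``dropped_positions`` records 0-based positions of non-standard residues
    removed on read (opt-in); consumers holding a PSSM for the original
    sequence must drop the same rows.
    """

    id: str
    residues: str
    dropped_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        for pos, aa in enumerate(self.residues):
            if aa not in AA_INDEX:
                raise ValidationError(
                    f"protein {self.id!r}: illegal residue {aa!r} at position "
                    f"{pos + 1} (not one of {CANONICAL_ORDER})"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RawPSSM:
    """L x 20 matrix of raw evolution scores in canonical column order."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM for {self.protein_id!r}: expected an Lx20 matrix, "
                f"got shape {scores.shape}"
            )
        if not np.all(np.isfinite(scores)):
            raise ValidationError(f"PSSM for {self.protein_id!r}: non-finite score")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]

    def drop_rows(self, positions: Sequence[int]) -> "RawPSSM":
        """Return a copy with the given 0-based rows removed (paired with
        sequences read under the drop-non-standard option)."""
        keep = np.setdiff1d(np.arange(len(self)), np.asarray(positions, dtype=int))
        return RawPSSM(self.protein_id, self.scores[keep])


@dataclass(frozen=True)
class DrugFingerprint:
    """A drug identifier plus its 256-component fingerprint vector.

    Components are held as reals; binary and counted fingerprints are both
    accepted.
    """

    id: str
    values: np.ndarray
    source: str = "table"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.shape != (N_FINGERPRINT,):
            raise ValidationError(
                f"fingerprint {self.id!r}: expected {N_FINGERPRINT} components, "
                f"got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError(f"fingerprint {self.id!r}: non-finite component")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class LabeledPair:
    """One (drug, protein) pair with label +1 (interactive), -1
    (non-interactive) or None (unlabeled, prediction input)."""

    drug_id: str
    protein_id: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (1, -1):
            raise ValidationError(
                f"pair ({self.drug_id!r}, {self.protein_id!r}): label must be "
                f"1 or -1, got {self.label!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_id, self.protein_id)


@dataclass
class Dataset:
    """A benchmark: labeled pairs plus the entity maps they reference."""

    pairs: list[LabeledPair]
    proteins: dict[str, ProteinSequence]
    pssms: dict[str, RawPSSM]
    fingerprints: dict[str, DrugFingerprint]
    metadata: dict = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return sum(1 for p in self.pairs if p.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for p in self.pairs if p.label == -1)

    def describe(self) -> dict[str, int]:
        """Counts of pairs, classes and distinct referenced entities."""
        drugs = {p.drug_id for p in self.pairs}
        prots = {p.protein_id for p in self.pairs}
        return {
            "n_pairs": len(self.pairs),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "n_drugs": len(drugs),
            "n_proteins": len(prots),
        }


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, *, nonstandard: str = "error") -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file.

    Residues are uppercased. Non-standard codes (B, J, O, U, X, Z) raise a
    validation error by default; with ``nonstandard="drop"`` the offending
    positions are removed and recorded in ``dropped_positions`` so the
    matching PSSM rows can be dropped too.
    """
    if nonstandard not in ("error", "drop"):
        raise ValueError(f"nonstandard must be 'error' or 'drop', got {nonstandard!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[ProteinSequence] = []
    for rec in records:
        residues = str(rec.seq).upper()
        dropped: tuple[int, ...] = ()
        if nonstandard == "drop":
            positions = tuple(
                i for i, aa in enumerate(residues) if aa in NON_STANDARD
            )
            if positions:
                keep = [aa for aa in residues if aa not in NON_STANDARD]
                residues = "".join(keep)
                dropped = positions
        out.append(ProteinSequence(rec.id, residues, dropped))
    return out


def write_fasta(path: str | Path, proteins: Iterable[ProteinSequence]) -> None:
    with open(path, "w") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n")
            for i in range(0, len(prot.residues), 60):
                fh.write(prot.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_pssm_ascii(
    path: str | Path,
    expected_length: int | None = None,
    *,
    protein_id: str | None = None,
) -> RawPSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`RawPSSM`.

    Only the first 20 columns (position-specific log-odds scores) are used;
    they are remapped from PSI-BLAST column order
    (``A R N D C Q E G H I L K M F P S T W Y V``) to the canonical
    alphabetical order. The weighted-percentage columns and the trailing
    information-content fields, if present, are ignored.
    """
    path = Path(path)
    rows: list[list[float]] = []
    residues: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            # data row: running index, residue letter, >= 20 numeric scores
            if len(tokens) >= 2 and _is_int(tokens[0]) and tokens[1].isalpha() and len(tokens[1]) == 1:
                cells = tokens[2:22]
                if len(cells) < 20:
                    raise FormatError(
                        f"{path}:{lineno}: expected at least 20 score columns, "
                        f"found {len(cells)}"
                    )
                try:
                    rows.append([float(c) for c in cells])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score cell: {exc}") from None
                residues.append(tokens[1].upper())
    if not rows:
        raise FormatError(f"{path}: no PSSM score rows found")
    if expected_length is not None and len(rows) != expected_length:
        raise FormatError(
            f"{path}: {len(rows)} PSSM rows but expected {expected_length}"
        )
    scores = np.asarray(rows, dtype=float)[:, PSIBLAST_TO_CANONICAL]
    return RawPSSM(protein_id if protein_id is not None else path.stem, scores)


def write_pssm_ascii(path: str | Path, pssm: RawPSSM, residues: str | None = None) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (scores only, integer-rounded
    to match the native format)."""
    file_order = pssm.scores[:, CANONICAL_TO_PSIBLAST]
    seq = residues if residues is not None else "A" * len(pssm)
    if len(seq) != len(pssm):
        raise ValidationError(
            f"residue string length {len(seq)} does not match PSSM rows {len(pssm)}"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, row in enumerate(file_order):
            cells = " ".join(f"{int(round(v)):3d}" for v in row)
            fh.write(f"{i + 1:5d} {seq[i]}  {cells}\n")


def read_pssm_dir(
    directory: str | Path,
    proteins: Iterable[ProteinSequence],
    *,
    suffix: str = ".pssm",
) -> dict[str, RawPSSM]:
    """Load ``<id><suffix>`` PSSM files for each protein, validating lengths
    and dropping rows for any positions removed at FASTA read time."""
    directory = Path(directory)
    out: dict[str, RawPSSM] = {}
    for prot in proteins:
        fp = directory / f"{prot.id}{suffix}"
        if not fp.exists():
            raise FormatError(f"missing PSSM file for protein {prot.id!r}: {fp}")
        original_length = len(prot) + len(prot.dropped_positions)
        pssm = read_pssm_ascii(fp, expected_length=original_length, protein_id=prot.id)
        if prot.dropped_positions:
            pssm = pssm.drop_rows(prot.dropped_positions)
        out[prot.id] = pssm
    return out


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            yield lineno, stripped.split("\t")


def read_fingerprint_table(path: str | Path) -> list[DrugFingerprint]:
    """Read a TSV of drug id + 256 numeric fingerprint components per row."""
    path = Path(path)
    out: list[DrugFingerprint] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) != 1 + N_FINGERPRINT:
            raise FormatError(
                f"{path}:{lineno}: expected id + {N_FINGERPRINT} values, "
                f"got {len(fields)} fields"
            )
        drug_id = fields[0]
        if drug_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate drug id {drug_id!r}")
        seen.add(drug_id)
        try:
            values = np.array([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value: {exc}") from None
        out.append(DrugFingerprint(drug_id, values))
    if not out:
        raise FormatError(f"{path}: no fingerprint rows found")
    return out


def write_fingerprint_table(path: str | Path, fingerprints: Iterable[DrugFingerprint]) -> None:
    with open(path, "w") as fh:
        for fp in fingerprints:
            vals = "\t".join(_format_number(v) for v in fp.values)
            fh.write(f"{fp.id}\t{vals}\n")


def _format_number(v: float) -> str:
    if math.isfinite(v) and v == int(v):
        return str(int(v))
    return repr(float(v))


def normalize_drug_id(drug_id: str) -> str:
    """Accept KEGG drug accessions with or without the leading ``#``."""
    return drug_id.lstrip("#")


def read_pairs(path: str | Path) -> list[LabeledPair]:
    """Read a TSV pair list: drug_id, protein_id, optional label in {1, -1}."""
    path = Path(path)
    out: list[LabeledPair] = []
    seen: set[tuple[str, str]] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) not in (2, 3):
            raise FormatError(
                f"{path}:{lineno}: expected 2 or 3 fields, got {len(fields)}"
            )
        drug_id = normalize_drug_id(fields[0])
        protein_id = fields[1]
        label: int | None = None
        if len(fields) == 3:
            try:
                label = int(fields[2])
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: label must be 1 or -1, got {fields[2]!r}"
                ) from None
            if label not in (1, -1):
                raise ValidationError(
                    f"{path}:{lineno}: label must be 1 or -1, got {label}"
                )
        key = (drug_id, protein_id)
        if key in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate pair {key}")
        seen.add(key)
        out.append(LabeledPair(drug_id, protein_id, label))
    return out


def write_pairs(path: str | Path, pairs: Iterable[LabeledPair]) -> None:
    with open(path, "w") as fh:
        for pair in pairs:
            if pair.label is None:
                fh.write(f"{pair.drug_id}\t{pair.protein_id}\n")
            else:
                fh.write(f"{pair.drug_id}\t{pair.protein_id}\t{pair.label}\n")


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def assemble_dataset(
    pairs: Sequence[LabeledPair],
    proteins: Mapping[str, ProteinSequence],
    pssms: Mapping[str, RawPSSM],
    fingerprints: Mapping[str, DrugFingerprint],
    metadata: Mapping | None = None,
) -> Dataset:
    """Cross-validate references and build a :class:`Dataset`.

    Every pair's drug id must resolve in ``fingerprints`` and its protein id
    in both ``proteins`` and ``pssms``; PSSM row counts must match sequence
    lengths.
    """
    missing: list[str] = []
    for pair in pairs:
        if pair.drug_id not in fingerprints:
            missing.append(f"drug {pair.drug_id!r}")
        if pair.protein_id not in proteins:
            missing.append(f"protein {pair.protein_id!r}")
        elif pair.protein_id not in pssms:
            missing.append(f"PSSM for protein {pair.protein_id!r}")
    if missing:
        unique = sorted(set(missing))
        raise ValidationError(
            f"unresolved identifiers in pair list: {', '.join(unique)}"
        )
    for pid, prot in proteins.items():
        if pid in pssms and len(pssms[pid]) != len(prot):
            raise ValidationError(
                f"protein {pid!r}: sequence length {len(prot)} != "
                f"PSSM rows {len(pssms[pid])}"
            )
    meta = {"psiblast_provenance": dict(PSIBLAST_PROVENANCE)}
    if metadata:
        meta.update(metadata)
    return Dataset(
        pairs=list(pairs),
        proteins=dict(proteins),
        pssms=dict(pssms),
        fingerprints=dict(fingerprints),
        metadata=meta,
    )


def get_fingerprint(store: Mapping[str, DrugFingerprint], drug_id: str) -> DrugFingerprint:
    """Look up a stored fingerprint; unknown ids raise :class:`UnknownIDError`."""
    drug_id = normalize_drug_id(drug_id)
    try:
        return store[drug_id]
    except KeyError:
        raise UnknownIDError(
            f"unknown drug id {drug_id!r}; {len(store)} fingerprints loaded"
        ) from None
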