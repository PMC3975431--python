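"""Drug representation: the 256-component fingerprint vector.

The canonical path is table lookup of precomputed fingerprint vectors
(:func:`dtipred.io.read_fingerprint_table` + :func:`get_fingerprint`). For
drugs without a precomputed vector, :func:`hashed_fingerprint_fallback`
computes a 256-bit path-based hashed fingerprint from a structure. The
fallback is a standard topological fingerprint, not a reproduction of the
specific 2D fingerprint the precomputed tables were built with; its output is
flagged ``source="fallback"`` so downstream code can tell the two apart.
"""

from __future__ import annotations

from pathlib import Path

from .errors import FormatError
from .io import DrugFingerprint, N_FINGERPRINT, get_fingerprint  # noqa: F401

__all__ = ["get_fingerprint", "hashed_fingerprint_fallback", "N_FINGERPRINT"]


def _parse_structure(structure: str | Path):
    """Accept a SMILES string, a MOL/SDF file path, or a MOL block."""
    from rdkit import Chem

    mol = None
    text = str(structure)
    path = Path(text)
    if path.suffix.lower() in (".mol", ".sdf") and path.exists():
        mol = Chem.MolFromMolFile(str(path))
    elif "\n" in text:  # multi-line input: treat as a MOL block
        mol = Chem.MolFromMolBlock(text)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise FormatError(f"could not parse drug structure input: {text[:80]!r}")
    return mol


def hashed_fingerprint_fallback(
    structure: str | Path,
    drug_id: str = "unknown",
    n_bits: int = N_FINGERPRINT,
    max_path: int = 7,
) -> DrugFingerprint:
    """Compute a hashed path fingerprint folded into ``n_bits`` bits.

    Linear-path fragments of up to ``max_path`` bonds are enumerated on the
    molecular graph, hashed, and folded into the bit vector (RDKit's
    topological fingerprint). The result is deterministic and invariant to
    atom input order, since the enumeration works on the canonicalized graph.
    """
    from rdkit.Chem import RDKFingerprint

    mol = _parse_structure(structure)
    bits = RDKFingerprint(mol, fpSize=n_bits, maxPath=max_path)
    values = [float(bits.GetBit(i)) for i in range(n_bits)]
    return DrugFingerprint(drug_id, values, source="fallback")
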