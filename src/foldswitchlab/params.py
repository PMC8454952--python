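"""Versioned parameter tables for the transferable energy terms.

The pairwise contact matrix and the burial propensities ship as TSV data
files; their SHA-256 checksums are recorded here and verified on load so a
run manifest can state exactly which parameterization produced a result.
"""

from __future__ import annotations

import hashlib
from functools import lru_cache
from importlib import resources

import numpy as np

from .chain import AMINO_ACIDS

PARAMETER_CHECKSUMS = {
    "contact_matrix.tsv":
        "e407c84a13ca6464369971917793b8478179cbfad55dd586299ca39bcdecc2f9",
    "burial_propensities.tsv":
        "92a0784ca71e0f835e63a0f7f2aa160bacd2a82320564c3295583682092bcaea",
}


def _read_data(name: str) -> str:
    text = resources.files("foldswitchlab.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    expected = PARAMETER_CHECKSUMS[name]
    if digest != expected:
        raise RuntimeError(
            f"parameter table {name} checksum mismatch: {digest} != {expected}")
    return text


@lru_cache(maxsize=None)
def contact_matrix() -> np.ndarray:
    """20x20 residue-pair well depths (kcal/mol), indexed by AMINO_ACIDS."""
    lines = [ln for ln in _read_data("contact_matrix.tsv").splitlines()
             if ln and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    assert "".join(header) == AMINO_ACIDS
    mat = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]])
    assert mat.shape == (20, 20)
    return mat


@lru_cache(maxsize=None)
def burial_propensities() -> np.ndarray:
    """20x3 burial well depths (kcal/mol): low / medium / high density."""
    lines = [ln for ln in _read_data("burial_propensities.tsv").splitlines()
             if ln and not ln.startswith("#")]
    mat = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]])
    assert mat.shape == (20, 3)
    return mat


def residue_type_indices(sequence: str) -> np.ndarray:
    """Map a one-letter sequence to row indices of the parameter tables."""
    return np.array([AMINO_ACIDS.index(a) for a in sequence], np.int64)
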