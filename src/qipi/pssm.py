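"""PSI-BLAST ASCII PSSM profiles (the ``-out_ascii_pssm`` dialect).

Only the first 20-column integer block (position-specific substitution
scores) is read.  A profile is aligned to one chain by position order: row k
corresponds to the chain's k-th residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .constants import AA_INDEX, AMINO_ACIDS
from .errors import AlignmentError, FormatError

HEADER = (
    "Last position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative "
    "weight of gapless real matches to pseudocounts"
)


@dataclass
class PssmProfile:
    """Per-position substitution scores for one chain."""

    residues: List[str]  # one-letter sequence, aligned to chain order
    scores: np.ndarray  # (L, 20) ints in AMINO_ACIDS column order
    chain_id: Optional[str] = None
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.shape != (len(self.residues), 20):
            raise AlignmentError(
                f"PSSM shape {self.scores.shape} does not match "
                f"{len(self.residues)} residues x 20 columns"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def self_score(self, position: int) -> int:
        """C_ir: the substitution score of the position's own residue type."""
        aa = self.residues[position]
        if aa not in AA_INDEX:
            raise AlignmentError(f"position {position}: nonstandard residue {aa!r}")
        return int(self.scores[position, AA_INDEX[aa]])

    @classmethod
    def from_text(cls, text: str, chain_id: Optional[str] = None,
                  source: Optional[str] = None) -> "PssmProfile":
        residues: List[str] = []
        rows: List[List[int]] = []
        in_block = False
        for line in text.splitlines():
            tokens = line.split()
            if not in_block:
                # the column-header line lists the 20 residues (twice in
                # full PSI-BLAST output; the first 20 suffice)
                if len(tokens) >= 20 and tokens[:20] == list(AMINO_ACIDS):
                    in_block = True
                continue
            if len(tokens) < 22:
                if residues:
                    break  # end of score block
                continue
            try:
                int(tokens[0])
            except ValueError:
                break
            aa = tokens[1]
            try:
                scores = [int(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise FormatError(f"malformed PSSM row: {line!r}") from exc
            residues.append(aa)
            rows.append(scores)
        if not rows:
            raise FormatError("no PSSM score rows found")
        return cls(residues, np.array(rows, dtype=int), chain_id, source)

    @classmethod
    def from_file(cls, path, chain_id: Optional[str] = None) -> "PssmProfile":
        path = Path(path)
        return cls.from_text(path.read_text(), chain_id, source=str(path))

    def to_text(self) -> str:
        lines = ["", HEADER]
        lines.append("            " + "   ".join(AMINO_ACIDS))
        for i, aa in enumerate(self.residues):
            row = " ".join(f"{int(v):3d}" for v in self.scores[i])
            # pad with the weighted-percentage block PSI-BLAST also prints
            pct = " ".join("  0" for _ in range(20))
            lines.append(f"{i + 1:5d} {aa} {row}  {pct}  0.00 0.00")
        lines.append("")
        return "\n".join(lines)

    def write(self, path) -> None:
        Path(path).write_text(self.to_text())


def check_alignment(profile: PssmProfile, chain_residues: Sequence) -> None:
    """Raise AlignmentError unless the profile matches the chain's sequence."""
    seq = [r.res_type for r in chain_residues]
    if len(seq) != len(profile):
        raise AlignmentError(
            f"PSSM has {len(profile)} rows but chain has {len(seq)} residues"
        )
    bad = [
        i for i, (a, b) in enumerate(zip(profile.residues, seq))
        if b != "X" and a != b
    ]
    if bad:
        raise AlignmentError(f"PSSM sequence mismatch at positions {bad[:10]}")
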