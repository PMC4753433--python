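"""Per-residue deuteration heat maps and PDB B-factor export.

Each covered residue takes the %D of its smallest enclosing resolved
region/peptide (finer regions win over their parent peptides); uncovered
residues are flagged.  Values can be written into the B-factor column of a
PDB copy for structure coloring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import pandas as pd

__all__ = ["RegionValue", "residue_heatmap", "write_bfactor_pdb"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionValue:
    """A resolved region (or whole peptide) with its %D value."""

    start: int
    end: int
    percent_D: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid span {self.start}-{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def residue_heatmap(regions: list[RegionValue], protein_length: int) -> pd.DataFrame:
    """Per-residue %D table under the smallest-enclosing-span rule.

    Columns: residue (1-based), percent_D (NaN if uncovered), covered (bool),
    source span.
    """
    rows = []
    by_span = sorted(regions, key=lambda r: r.span)
    for pos in range(1, protein_length + 1):
        hit = next((r for r in by_span if r.start <= pos <= r.end), None)
        rows.append({
            "residue": pos,
            "percent_D": hit.percent_D if hit else float("nan"),
            "covered": hit is not None,
            "source": f"{hit.start}-{hit.end}" if hit else "",
        })
    return pd.DataFrame(rows)


def write_bfactor_pdb(heatmap: pd.DataFrame, pdb_in: str, pdb_out: str,
                      chain: str | None = None,
                      residue_offset: int = 0) -> int:
    """Write a PDB copy with per-residue %D in the B-factor column.

    ``residue_offset`` maps analysis numbering to PDB numbering
    (pdb_number = analysis_number + offset).  Uncovered residues keep B = 0;
    PDB residues absent from the map are logged and skipped.  Returns the
    number of residues written.  The PDB fixed format renders B-factors with
    two decimals.
    """
    values = {int(r.residue) + residue_offset: float(r.percent_D)
              for r in heatmap.itertuples() if r.covered}
    st = gemmi.read_structure(pdb_in)
    written = 0
    seen: set[int] = set()
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                num = res.seqid.num
                seen.add(num)
                b = values.get(num, 0.0)
                if num in values:
                    written += 1
                for atom in res:
                    atom.b_iso = round(b, 2)
    for num in sorted(set(values) - seen):
        log.warning("residue %d absent from PDB; skipped", num)
    st.write_pdb(pdb_out)
    return written
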