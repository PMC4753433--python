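"""Plain-text I/O: CSV tables with metadata header blocks, FASTA, YAML config."""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .peptides import Peptide, ProteinSequence

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_table",
    "read_table",
    "write_fasta",
    "read_fasta",
    "write_peptides_csv",
    "read_peptides_csv",
    "read_dose_response_csv",
]

DOSE_RESPONSE_COLUMNS = ["construct", "mode", "varied_side", "conc_uM",
                         "rate", "rate_sd", "n"]


@dataclass
class RunConfig:
    """Validated run settings; every default is recorded in output metadata."""

    seed: int = 0
    temperature_K: float = 308.15
    label_fraction: float = 0.8
    concentration_unit: str = "uM"
    exposure_times_s: list[float] = field(default_factory=lambda: [15.0, 120.0, 1200.0])
    noise_cv_flux: float = 0.05
    noise_cv_hdx: float = 0.03
    n_replicates: int = 3
    cat_frac: float = 0.25
    kint_band: list[float] = field(default_factory=lambda: [0.1, 0.35])
    kint_fold: float = 4.0
    aicc_margin: float = 20.0
    min_component_weight: float = 0.02
    centroid_tol_Da: float = 0.15
    n_term_loss: int = 1
    pdb_path: str | None = None
    pdb_chain: str | None = None
    pdb_residue_offset: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must be in (0, 1]")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")
        if self.noise_cv_flux < 0 or self.noise_cv_hdx < 0:
            raise ValueError("noise CVs must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file, applying keyword overrides."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                metadata: dict | None = None) -> None:
    """CSV with a '# key: value' metadata header block."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a metadata-headed CSV back into (frame, metadata)."""
    meta: dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)))
    return df, meta


def read_dose_response_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a dose-response table (flux-assay CSV)."""
    df, _ = read_table(path)
    missing = [c for c in DOSE_RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing dose-response columns {missing}")
    bad = df.index[~(df["conc_uM"] > 0)].tolist()
    if bad:
        raise ValueError(
            f"{path}: non-positive concentration at data row(s) {bad}")
    return df


def write_fasta(seq: ProteinSequence, path: str | Path,
                name: str = "fixture") -> None:
    rec = SeqRecord(Seq(seq.residues), id=name, description="")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> ProteinSequence:
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ProteinSequence(str(rec.seq))


def write_peptides_csv(peptides: list[Peptide], path: str | Path) -> None:
    df = pd.DataFrame([{"id": p.id, "start": p.start, "end": p.end,
                        "sequence": p.sequence, "charge": p.charge}
                       for p in peptides])
    df.to_csv(path, index=False)


def read_peptides_csv(path: str | Path) -> list[Peptide]:
    df = pd.read_csv(path)
    return [Peptide(str(r.id), int(r.start), int(r.end), str(r.sequence),
                    int(r.charge)) for r in df.itertuples()]
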