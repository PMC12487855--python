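"""File readers/writers and run manifests.

All on-disk formats are plain text: counts and phenotype tables as TSV
with explicit headers, libraries as CSV, gene sets as GMT, expression as
dense TSV (cells x genes) or MatrixMarket triplets with sidecar gene/cell
lists.  Every CLI invocation writes a JSON RunManifest (command,
parameters, input checksums, seed, version, timestamp) sufficient to
reproduce a seeded run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import CountTable
from .exceptions import ScreenStateError
from .library import SgRNALibrary
from .screen import ScreenConfig

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_library",
    "write_library",
    "read_expression",
    "write_expression",
    "read_screen_config",
    "RunManifest",
]

log = logging.getLogger(__name__)


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# -- count tables -----------------------------------------------------------


def read_count_table(counts_path, samples_path, library: SgRNALibrary | None = None) -> CountTable:
    """Read a counts TSV (first column element ids, header = sample ids)
    plus a sample-metadata TSV (columns sample, condition, replicate).

    With a library, rows are aligned to it: unknown elements are reported
    on the returned table (``unknown_elements``) and excluded, missing
    elements are filled with 0 and logged.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.all(np.mod(arr, 1) == 0):
        bad = np.argwhere(~np.equal(np.mod(arr.astype(float), 1), 0))
        r, c = (bad[0] if len(bad) else (0, 0))
        raise ScreenStateError(
            f"{counts_path}: non-integer count at element "
            f"{counts.index[r]!r}, sample {counts.columns[c]!r}"
        )
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ScreenStateError(
            f"{counts_path}: negative count at element "
            f"{counts.index[r]!r}, sample {counts.columns[c]!r}"
        )
    meta = pd.read_csv(samples_path, sep="\t").set_index("sample")
    table = CountTable(counts=counts.astype(np.int64), sample_meta=meta)
    if library is not None:
        aligned = table.aligned_to(library)
        unknown = getattr(aligned, "unknown_elements", [])
        if unknown:
            log.warning("%d element(s) not in the library were excluded", len(unknown))
        n_missing = len(set(library.element_ids) - set(table.counts.index))
        if n_missing:
            log.warning("%d library element(s) absent from counts filled with 0", n_missing)
        return aligned
    return table


def write_count_table(table: CountTable, counts_path, samples_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="element_id")
    table.sample_meta.to_csv(samples_path, sep="\t", index_label="sample")


# -- libraries --------------------------------------------------------------


def read_library(path, species: str = "unspecified") -> SgRNALibrary:
    """Read a library CSV with columns element_id, gene, is_ntc, protospacer."""
    df = pd.read_csv(path, dtype={"element_id": str, "gene": str, "protospacer": str})
    if "is_ntc" not in df.columns:
        raise ScreenStateError(f"{path}: missing is_ntc column")
    df["is_ntc"] = df["is_ntc"].astype(str).str.lower().isin(("true", "1", "yes"))
    return SgRNALibrary.from_frame(df, species=species)


def write_library(library: SgRNALibrary, path) -> None:
    library.to_frame().to_csv(path, index=False)


# -- expression matrices ----------------------------------------------------


def read_expression(path, genes_path=None, cells_path=None) -> pd.DataFrame:
    """Read a cells x genes expression matrix.

    Dense TSV (rows = cell ids, header = gene symbols) by default; a
    ``.mtx`` path is read as MatrixMarket triplets with required sidecar
    gene and cell lists (one id per line), oriented genes x cells as is
    conventional, and transposed to cells x genes.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        if genes_path is None or cells_path is None:
            raise ScreenStateError("MTX input requires gene and cell list files")
        mat = mmread(path).toarray()
        genes = [line.strip() for line in open(genes_path, encoding="utf-8") if line.strip()]
        cells = [line.strip() for line in open(cells_path, encoding="utf-8") if line.strip()]
        if mat.shape != (len(genes), len(cells)):
            raise ScreenStateError(
                f"MTX shape {mat.shape} does not match {len(genes)} genes x {len(cells)} cells"
            )
        return pd.DataFrame(mat.T, index=pd.Index(cells, name="cell_id"), columns=genes)
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="cell_id")


# -- configuration ----------------------------------------------------------


def read_screen_config(path) -> ScreenConfig:
    """Read a YAML/JSON key-value file mirroring ScreenConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ScreenStateError(f"{path}: config must be a mapping")
    allowed = {"doublings", "pseudocount", "target_depth", "alpha", "top_k"}
    unknown = set(raw) - allowed
    if unknown:
        raise ScreenStateError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return ScreenConfig(**raw)


# -- manifests --------------------------------------------------------------


@dataclass
class RunManifest:
    """Reproducibility record emitted beside every CLI output."""

    command: str
    parameters: dict
    seed: int | None
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    notes: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _checksum(path)

    def write(self, out_dir) -> Path:
        out = Path(out_dir) / f"manifest_{self.command.replace(' ', '_')}.json"
        payload = {
            "command": self.command,
            "parameters": self.parameters,
            "seed": self.seed,
            "inputs": self.inputs,
            "notes": self.notes,
            "version": self.version,
            "timestamp": self.timestamp,
        }
        with open(out, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")
        return out
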