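"""OTU count tables and their on-disk formats.

The count table is the lingua franca of the empirical half of the package:
rows are OTUs, columns are samples (cultivation wells plus the raw
community), and cells are non-negative integer read counts.  Two formats
are supported: a plain TSV whose first column is ``OTU_ID``, and the BIOM
v1.0 JSON flavour (sparse), which is plain JSON and round-trips exactly.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["OtuTable"]


class OtuTable:
    """Integer read counts indexed by OTU ID x sample ID.

    Parameters
    ----------
    counts
        DataFrame with OTU IDs as the index and sample IDs as columns.
        Values must be non-negative integers; IDs must be unique.
    """

    def __init__(self, counts: pd.DataFrame):
        counts = counts.copy()
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate OTU ID {dup!r}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        arr = counts.to_numpy()
        if arr.size:
            bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) % 1 != 0)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValueError(
                    f"non-integer count at OTU {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}: {arr[r, c]!r}"
                )
            if (arr.astype(float) < 0).any():
                r, c = np.argwhere(arr.astype(float) < 0)[0]
                raise ValueError(
                    f"negative count at OTU {counts.index[r]!r}, "
                    f"sample {counts.columns[c]!r}: {arr[r, c]!r}"
                )
        self.counts = counts.astype(np.int64)

    # -- basic views ---------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples stay all-zero."""
        depths = self.counts.sum(axis=0).astype(float)
        depths[depths == 0] = np.nan
        rel = self.counts / depths
        return rel.fillna(0.0)

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix (>= 1 read)."""
        return self.counts > 0

    def drop_empty_otus(self) -> "OtuTable":
        """Remove OTUs with zero reads in every sample; order preserved."""
        keep = self.counts.sum(axis=1) > 0
        return OtuTable(self.counts.loc[keep])

    def select_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[:, list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"OtuTable({self.n_otus} OTUs x {self.n_samples} samples)"

    # -- TSV -----------------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "OtuTable":
        """Read a tab-separated table whose first column is ``OTU_ID``."""
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if df.columns[0] != "OTU_ID":
            raise ValueError(
                f"{path}: first column must be 'OTU_ID', got {df.columns[0]!r}"
            )
        df = df.set_index("OTU_ID")
        for col in df.columns:
            parsed = pd.to_numeric(df[col], errors="coerce")
            if parsed.isna().any():
                row = df.index[parsed.isna()][0]
                raise ValueError(
                    f"{path}: unparseable count at OTU {row!r}, sample {col!r}"
                )
            df[col] = parsed
        return cls(df)

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "OTU_ID"
        out.to_csv(path, sep="\t")

    # -- BIOM v1.0 (JSON flavour) --------------------------------------

    @classmethod
    def read_biom_json(cls, path) -> "OtuTable":
        with open(path) as fh:
            doc = json.load(fh)
        shape = doc["shape"]
        otus = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros(shape, dtype=np.int64)
        if doc.get("matrix_type", "sparse") == "sparse":
            for r, c, v in doc["data"]:
                mat[r, c] = v
        else:
            mat[:] = np.asarray(doc["data"])
        return cls(pd.DataFrame(mat, index=otus, columns=samples))

    def write_biom_json(self, path) -> None:
        rows, cols = np.nonzero(self.counts.to_numpy())
        data = [
            [int(r), int(c), int(self.counts.iat[r, c])] for r, c in zip(rows, cols)
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "nomvote",
            "date": datetime.datetime.now().isoformat(),
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [self.n_otus, self.n_samples],
            "rows": [{"id": o, "metadata": None} for o in self.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": data,
        }
        Path(path).write_text(json.dumps(doc))
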