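"""Reading, validation and writing of the pipeline's tabular formats.

Supported inputs are a genes-by-samples count matrix (TSV, first column
gene IDs, header row of sample IDs), per-sample two-column htseq-count
output, a sample metadata table, GFF3 gene annotations and a flat
gene-to-GO-term table.  All outputs are TSV plus a JSON run manifest.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("parent1", "parent2", "hybrid")
CHROM_CATEGORIES = ("autosome", "Z", "unanchored")

#: chromosome names treated as the Z sex chromosome (case-insensitive)
DEFAULT_Z_ALIASES = ("Z", "chrZ")


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    gene_ids: np.ndarray
    sample_ids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            flt = np.asarray(self.counts, dtype=float)
            frac = flt % 1 != 0
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise ValueError(
                    f"non-integer count for gene {self.gene_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}: {flt[i, j]!r}"
                )
            self.counts = flt.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set = set()
                dups = sorted({x for x in ids if x in seen or seen.add(x)})
                raise ValueError(f"duplicate {label} IDs: {dups}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(
            gene_ids=df.index.to_numpy(dtype=object),
            sample_ids=df.columns.to_numpy(dtype=object),
            counts=df.to_numpy(),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Sub-matrix restricted to ``sample_ids`` (order preserved)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(self.gene_ids.copy(),
                           np.asarray(list(sample_ids), dtype=object),
                           self.counts[:, idx])

    def select_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            return CountMatrix(self.gene_ids[mask], self.sample_ids.copy(),
                               self.counts[mask])
        return CountMatrix(self.gene_ids[mask], self.sample_ids.copy(),
                           self.counts[mask])


def read_counts(path, dialect: str = "matrix-tsv") -> CountMatrix:
    """Read a count matrix.

    ``dialect="matrix-tsv"``: a single TSV, first column gene IDs, one
    column per sample.  ``dialect="htseq-per-sample"``: a list of
    two-column TSV files (gene, count), one per sample; the trailing
    ``__no_feature``-style summary rows htseq-count appends are dropped
    and the sample ID is the file's stem.  All per-sample files must
    cover the same gene set.
    """
    if dialect == "matrix-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return CountMatrix.from_frame(df)
    if dialect == "htseq-per-sample":
        paths = [Path(p) for p in (path if isinstance(path, (list, tuple)) else [path])]
        series = []
        for p in paths:
            s = pd.read_csv(p, sep="\t", header=None, index_col=0).iloc[:, 0]
            s.index = s.index.astype(str)
            s = s[~s.index.str.startswith("__")]
            s.name = p.stem
            series.append(s)
        ref = set(series[0].index)
        for s in series[1:]:
            diff = ref.symmetric_difference(s.index)
            if diff:
                raise ValueError(
                    f"gene sets differ between {series[0].name!r} and "
                    f"{s.name!r}; symmetric difference: {sorted(diff)[:20]}"
                )
        df = pd.concat([s.reindex(series[0].index) for s in series], axis=1)
        df.index.name = "gene_id"
        return CountMatrix.from_frame(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_counts(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t")


def read_sample_table(path) -> pd.DataFrame:
    """Read sample metadata (columns sample_id, group, tissue)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample table must have columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(
            f"duplicate sample IDs: {sorted(df.loc[df.sample_id.duplicated(), 'sample_id'])}"
        )
    return df


def validate_samples(cm: CountMatrix, samples: pd.DataFrame) -> None:
    """Check every matrix sample appears exactly once in the metadata."""
    meta = set(samples["sample_id"])
    missing = [s for s in cm.sample_ids if s not in meta]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")


def read_gff_gene_map(
    path,
    anchored_chroms: Iterable[str],
    id_attribute: str = "ID",
    z_aliases: Iterable[str] = DEFAULT_Z_ALIASES,
) -> pd.DataFrame:
    """Extract gene -> chromosome assignments from a GFF3 file.

    Only ``gene`` features are read.  Each gene is categorised as "Z" if
    its chromosome matches one of ``z_aliases`` (case-insensitive),
    "autosome" if the chromosome is in ``anchored_chroms``, and
    "unanchored" otherwise.  GFF3 coordinates are 1-based inclusive but
    only the sequence name and attributes are used here.

    Returns a DataFrame with columns gene_id, chromosome, chrom_category.
    """
    z_upper = {z.upper() for z in z_aliases}
    anchored = set(anchored_chroms)
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _source, ftype = fields[0], fields[1], fields[2]
            if ftype != "gene":
                continue
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            if id_attribute not in attrs:
                raise ValueError(
                    f"{path}: line {lineno}: gene feature lacks "
                    f"{id_attribute!r} attribute"
                )
            gid = attrs[id_attribute]
            if gid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate gene ID {gid!r}")
            seen.add(gid)
            if chrom.upper() in z_upper:
                cat = "Z"
            elif chrom in anchored:
                cat = "autosome"
            else:
                cat = "unanchored"
            records.append((gid, chrom, cat))
    return pd.DataFrame(records, columns=["gene_id", "chromosome", "chrom_category"])


def read_go_annotations(path) -> pd.DataFrame:
    """Read a flat gene-to-GO table (gene_id, term_id, term_name)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"GO annotation table must have columns {sorted(required)}")
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    dup = df.duplicated(subset=["gene_id", "term_id"])
    if dup.any():
        pairs = df.loc[dup, ["gene_id", "term_id"]].itertuples(index=False)
        raise ValueError(f"duplicate (gene, term) pairs: {list(pairs)[:10]}")
    return df


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    config: Mapping | None = None,
    seed: int | None = None,
    extra: Mapping | None = None,
) -> dict:
    """Write result tables as TSV plus a JSON run manifest.

    Floats are written with 17 significant digits so read-back is exact
    to double precision.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(config) if config is not None else None,
        "seed": seed,
        "tables": {},
        "versions": _versions(),
    }
    if extra:
        manifest.update(_jsonable(extra))
    for name, df in tables.items():
        fname = f"{name}.tsv"
        df.to_csv(out_dir / fname, sep="\t", index=False, float_format="%.17g")
        manifest["tables"][name] = {"file": fname, "n_rows": int(len(df))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "hybriddom": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        obj = asdict(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
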