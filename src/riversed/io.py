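"""Plain-text readers/writers for the pipeline's tables and matrices.

On disk, feature tables are TSV with features as rows and a header row of
sample ids (in memory they are samples x features DataFrames).  BIOM files
are supported when the ``biom`` package is installed.  Output files may carry
``# key: value`` provenance comment lines before the header.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from ._utils import RiversedError


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_feature_table(table: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a samples x features table as features x samples TSV."""
    path = Path(path)
    if path.suffix == ".biom":
        _write_biom(table, path)
        return
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        disk = table.T
        disk.index.name = "feature_id"
        fh.write(disk.to_csv(sep="\t", float_format="%.10g"))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (or .biom) into samples x features."""
    path = Path(path)
    if path.suffix == ".biom":
        return _read_biom(path)
    disk = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return disk.T


def _write_biom(table: pd.DataFrame, path: Path) -> None:
    try:
        from biom.table import Table
    except ImportError:  # pragma: no cover
        raise RiversedError("BIOM support requires the 'biom-format' package")
    bt = Table(table.T.to_numpy(), observation_ids=list(map(str, table.columns)),
               sample_ids=list(map(str, table.index)))
    with open(path, "w") as fh:
        fh.write(bt.to_json("riversed"))


def _read_biom(path: Path) -> pd.DataFrame:
    try:
        import biom
    except ImportError:  # pragma: no cover
        raise RiversedError("BIOM support requires the 'biom-format' package")
    bt = biom.load_table(str(path))
    return bt.to_dataframe(dense=True).T


def write_metadata(meta: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        out = meta.copy()
        out.index.name = "sample_id"
        fh.write(out.to_csv(sep="\t", float_format="%.10g"))


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_distance_matrix(dm, path: str | Path, provenance: dict | None = None) -> None:
    """Square TSV with an id header row/column."""
    import skbio

    if isinstance(dm, skbio.DistanceMatrix):
        df = dm.to_data_frame()
    else:
        df = pd.DataFrame(dm)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.index.name = "sample_id"
        fh.write(df.to_csv(sep="\t", float_format="%.10g"))


def read_distance_matrix(path: str | Path):
    import skbio

    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return skbio.DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()


def write_tidy(df: pd.DataFrame, path: str | Path, provenance: dict | None = None,
               index: bool = False) -> None:
    """Write a tidy results table with optional provenance comments."""
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write(df.to_csv(sep="\t", float_format="%.10g", index=index))
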