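"""TSV readers/writers for the pipeline's tabular interchange formats.

All stage outputs are plain tab-separated text with a header row so any
intermediate can be inspected, edited or re-fed to a later stage.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ABUNDANCE_COLS = ["probe_id", "gene_id", "signal_normoxia", "signal_hypoxia"]
TRUTH_COLS = ["gene_id", "expressed", "s_normoxia", "s_hypoxia"]
LIBRARY_COLS = ["probe_id", "gene_id", "efficacy"]
GROWTH_COLS = ["gene_id", "shrna", "condition", "replicate", "cell_count"]
CT_COLS = ["gene_id", "condition", "replicate", "ct"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _read(path: str | Path, required: list[str], dtype=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=dtype)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_abundance(path: str | Path) -> pd.DataFrame:
    return _read(path, ABUNDANCE_COLS, dtype={"probe_id": str, "gene_id": str})


def read_truth(path: str | Path) -> pd.DataFrame:
    return _read(path, TRUTH_COLS, dtype={"gene_id": str})


def read_growth(path: str | Path) -> pd.DataFrame:
    return _read(path, GROWTH_COLS, dtype={"gene_id": str, "shrna": str})


def read_ct(path: str | Path) -> pd.DataFrame:
    return _read(path, CT_COLS, dtype={"gene_id": str})


def read_gene_list(path: str | Path) -> set[str]:
    """One gene_id per line (the expressed-gene list format)."""
    return {
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    }


def write_gene_list(genes, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))
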