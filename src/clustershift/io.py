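"""Readers/writers for gene-set (GMT), signature and ranked-list (RNK) files.

All formats are tab-delimited UTF-8; lines starting with '#' are ignored.
GMT: set name, description, member genes.  RNK: gene, score.  Signatures are
accepted either as GMT or as a two-column (cell_type, gene) TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import ValidationError


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line (need name, desc, genes): {line[:60]!r}")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if name in sets:
            raise ValidationError(f"duplicate set name in GMT: {name!r}")
        if len(set(genes)) != len(genes):
            raise ValidationError(f"duplicate genes within set {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_signatures(path: str | Path) -> dict[str, list[str]]:
    """Signatures as GMT or two-column (cell_type, gene) TSV, autodetected."""
    text = Path(path).read_text()
    first = next((l for l in text.splitlines() if l.strip() and not l.startswith("#")), "")
    if len(first.split("\t")) >= 3:
        return read_gmt(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["cell_type", "gene"])
    out: dict[str, list[str]] = {}
    for ct, grp in df.groupby("cell_type", sort=False):
        genes = list(grp["gene"])
        if len(set(genes)) != len(genes):
            raise ValidationError(f"duplicate genes in signature {ct!r}")
        out[str(ct)] = genes
    return out


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    scores.rename("score").to_csv(path, sep="\t", header=False)


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, index_col=0,
                     names=["gene", "score"])
    return df["score"]
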