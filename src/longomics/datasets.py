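"""Core data containers for paired multi-omics abundance matrices.

The central object is :class:`MultiOmicsDataset`: two or more abundance
matrices (samples x analytes, on log2 scale, NaN = missing) aligned over the
same ordered samples, plus per-sample metadata (subject, genotype, timepoint,
sex, mixture) and optional analyte -> annotation-term maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["subject_id", "genotype", "timepoint", "age_months", "sex", "mixture"]


@dataclass
class MultiOmicsDataset:
    """Aligned per-block abundance matrices plus sample metadata.

    Parameters
    ----------
    blocks : dict of str -> pandas.DataFrame
        One matrix per omics block (e.g. ``"proteins"``, ``"metabolites"``),
        samples as rows (index = sample id), analytes as columns, values on
        log2 scale with ``NaN`` marking missing measurements.
    samples : pandas.DataFrame
        Indexed by sample id; columns ``subject_id``, ``genotype``,
        ``timepoint``, ``age_months``, ``sex``, ``mixture``.
    annotations : dict of str -> pandas.DataFrame, optional
        Per block, a long-format map with columns ``analyte_id`` and ``term``.
    """

    blocks: dict[str, pd.DataFrame]
    samples: pd.DataFrame
    annotations: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("dataset needs at least one block")
        ref = None
        for name, X in self.blocks.items():
            if ref is None:
                ref = X.index
            elif not X.index.equals(ref):
                raise ValueError(f"block {name!r} sample order differs from the first block")
        if not self.samples.index.equals(ref):
            raise ValueError("sample metadata index differs from block sample order")
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample metadata lacks columns: {missing_cols}")
        geno_per_subject = self.samples.groupby("subject_id")["genotype"].nunique()
        bad = geno_per_subject[geno_per_subject > 1]
        if len(bad):
            raise ValueError(f"subjects with more than one genotype: {list(bad.index)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def block_names(self) -> list[str]:
        return list(self.blocks)

    def subset_samples(self, sample_ids) -> "MultiOmicsDataset":
        """Return a new dataset restricted to ``sample_ids`` (order preserved)."""
        sample_ids = list(sample_ids)
        return MultiOmicsDataset(
            blocks={k: v.loc[sample_ids] for k, v in self.blocks.items()},
            samples=self.samples.loc[sample_ids],
            annotations=self.annotations,
        )

    def subset_timepoint(self, timepoint: str) -> "MultiOmicsDataset":
        keep = self.samples.index[self.samples["timepoint"] == timepoint]
        if len(keep) == 0:
            raise ValueError(f"timepoint {timepoint!r} not present in metadata")
        return self.subset_samples(keep)

    # ------------------------------------------------------------------ IO

    def to_dir(self, path) -> None:
        """Write blocks, metadata and annotations as TSV under ``path``.

        Block TSVs have the sample id as first column and analytes as the
        remaining columns; missing values are written as empty fields.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, X in self.blocks.items():
            X.to_csv(path / f"{name}.tsv", sep="\t", index_label="sample_id", na_rep="")
        self.samples.to_csv(path / "samples.tsv", sep="\t", index_label="sample_id")
        for name, ann in self.annotations.items():
            ann.to_csv(path / f"{name}.annotations.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path, block_names=None) -> "MultiOmicsDataset":
        """Load a dataset previously written by :meth:`to_dir`."""
        path = Path(path)
        samples = pd.read_csv(path / "samples.tsv", sep="\t", index_col="sample_id")
        if block_names is None:
            block_names = sorted(
                p.stem
                for p in path.glob("*.tsv")
                if p.name != "samples.tsv" and not p.name.endswith(".annotations.tsv")
            )
        blocks = {
            name: pd.read_csv(path / f"{name}.tsv", sep="\t", index_col="sample_id")
            for name in block_names
        }
        annotations = {}
        for name in block_names:
            ann_path = path / f"{name}.annotations.tsv"
            if ann_path.exists():
                annotations[name] = pd.read_csv(ann_path, sep="\t")
        return cls(blocks=blocks, samples=samples, annotations=annotations)


def read_annotation_map(path) -> pd.DataFrame:
    """Read a two-column (analyte id, term) TSV annotation map."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("annotation map needs two columns: analyte id, term")
    df = df.iloc[:, :2]
    df.columns = ["analyte_id", "term"]
    return df


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
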