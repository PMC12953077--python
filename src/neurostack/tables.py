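"""Feature tables: subjects x named features, tagged by feature set."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regions import default_tags


@dataclass
class FeatureTable:
    """A subjects-by-features table with a set tag per feature.

    ``data`` is indexed by subject id; ``tags`` maps each column to its
    feature-set tag (``MO-SV``, ``MO-CT``, ``MO-other``, ``MS``,
    ``GT-local``, ``GT-global``, ``ABETA``).
    """

    data: pd.DataFrame
    tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tags:
            known = default_tags()
            self.tags = {c: known.get(c, "untagged") for c in self.data.columns}
        missing = [c for c in self.data.columns if c not in self.tags]
        if missing:
            raise ValueError(f"columns without a set tag: {missing[:5]}")

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def columns_with_tags(self, tags: set[str] | list[str]) -> list[str]:
        tags = set(tags)
        return [c for c in self.data.columns if self.tags[c] in tags]

    def select_tags(self, tags: set[str] | list[str]) -> "FeatureTable":
        cols = self.columns_with_tags(tags)
        return FeatureTable(self.data[cols].copy(),
                            {c: self.tags[c] for c in cols})

    def subset(self, subject_ids) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(subject_ids)].copy(),
                            dict(self.tags))

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), dict(self.tags))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, tags: dict[str, str] | None = None) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        return cls(df, tags or {})


def concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Column-concatenate tables sharing the same subjects (order-aligned)."""
    if not tables:
        raise ValueError("no tables to concatenate")
    index = tables[0].data.index
    for t in tables[1:]:
        if set(t.data.index) != set(index):
            raise ValueError("subject-id mismatch between component tables")
    data = pd.concat([t.data.loc[index] for t in tables], axis=1)
    if data.columns.duplicated().any():
        raise ValueError("duplicate feature columns after concatenation")
    tags: dict[str, str] = {}
    for t in tables:
        tags.update(t.tags)
    return FeatureTable(data, tags)
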