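"""AAL parcellation labels, the cerebellar ROI filter, and lobe partitions.

The Automated Anatomical Labeling (AAL) atlas divides the brain into 116
regions; cerebellar and vermis regions are conventionally dropped from
source-level connectivity analyses for their lower reconstruction
reliability, leaving 90 regions.  Those 90 are grouped here into six
coarse divisions: the five lobes (frontal, insular, temporal, parietal,
occipital) plus the subcortical nuclei.

The shipped partition (``data/aal90_lobes.csv``) is a conventional
grouping — anterior and mid cingulate with the frontal lobe, posterior
cingulate with the parietal, Rolandic operculum with the frontal — and is
fully replaceable by any CSV with columns ``region_label,group``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "LOBE_GROUPS",
    "aal116_labels",
    "aal90_labels",
    "apply_roi_filter",
    "LobePartition",
    "default_lobe_partition",
]

LOBE_GROUPS = ("frontal", "insular", "temporal", "parietal", "occipital",
               "subcortical")

_CEREBELLAR_PREFIXES = ("Cerebelum", "Cerebellum", "Vermis")


def _data_text(name: str) -> str:
    return resources.files("plmnet.data").joinpath(name).read_text()


def aal116_labels() -> list[str]:
    """The packaged AAL-116 region labels, in atlas order."""
    return _data_text("aal116_labels.txt").split()


def aal90_labels() -> list[str]:
    """The 90 AAL labels that survive the cerebellar exclusion."""
    return apply_roi_filter(aal116_labels())


def apply_roi_filter(region_labels: list[str]) -> list[str]:
    """Drop cerebellar and vermis regions, preserving order.

    Labels must come from the packaged AAL-116 set; an unknown label is
    rejected (named in the error) rather than silently passed through.
    Idempotent: an already cerebellum-free list is returned unchanged.
    """
    known = set(aal116_labels())
    out = []
    for lab in region_labels:
        if lab not in known:
            raise ValueError(f"unknown region label {lab!r} (not in the AAL-116 set)")
        if not lab.startswith(_CEREBELLAR_PREFIXES):
            out.append(lab)
    return out


class LobePartition:
    """Total mapping from region labels to one of the six lobe groups."""

    def __init__(self, mapping: dict[str, str]):
        bad = {g for g in mapping.values()} - set(LOBE_GROUPS)
        if bad:
            raise ValueError(f"unknown lobe group(s): {sorted(bad)}")
        self.mapping = dict(mapping)
        present = {g for g in self.mapping.values()}
        missing = set(LOBE_GROUPS) - present
        if missing:
            raise ValueError(f"empty lobe group(s): {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.mapping)

    def group_of(self, label: str) -> str:
        try:
            return self.mapping[label]
        except KeyError:
            raise ValueError(f"region {label!r} missing from the lobe partition") from None

    def members(self, group: str) -> list[str]:
        return [r for r, g in self.mapping.items() if g == group]

    @classmethod
    def from_csv(cls, path) -> "LobePartition":
        df = pd.read_csv(path)
        if not {"region_label", "group"} <= set(df.columns):
            raise ValueError("partition CSV needs columns region_label,group")
        if df["region_label"].duplicated().any():
            dup = df.loc[df["region_label"].duplicated(), "region_label"].iloc[0]
            raise ValueError(f"duplicate region {dup!r} in partition")
        return cls(dict(zip(df["region_label"], df["group"])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_label": list(self.mapping), "group": list(self.mapping.values())}
        )


def default_lobe_partition() -> LobePartition:
    """The packaged conventional AAL-90 lobe partition."""
    from io import StringIO

    return LobePartition.from_csv(StringIO(_data_text("aal90_lobes.csv")))
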