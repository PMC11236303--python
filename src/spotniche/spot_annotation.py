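"""Per-spot region and marker-group annotation.

Tumor spots are partitioned by a marker gene (CDKN2A in the motivating
analysis) into positive / negative / other; "other" typically marks necrotic
tumor excluded from group statistics. Non-tumor spots later receive a
nearby-group from the neighborhood module. A manual-override channel mirrors
curation of automatic calls.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

import pandas as pd

from .io_formats import CountMatrix

TUMOR_GROUPS = {"pos", "neg", "other", "not_applicable"}
NEARBY_GROUPS = {
    "nearby_pos",
    "nearby_neg",
    "nearby_both",
    "nearby_none",
    "not_applicable",
    "unclassified",  # sentinel: non-tumor spot not yet classified
}
PROVENANCE = {"automatic", "manual"}
FIELDS = ("region", "tumor_group", "nearby_group", "provenance")


class AnnotationError(ValueError):
    pass


@dataclass
class SpotAnnotation:
    """Region label, tumor marker-group and nearby-group per spot.

    Backed by a DataFrame indexed by spot_id with columns
    region / tumor_group / nearby_group / provenance.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in FIELDS if c not in t.columns]
        if missing:
            raise AnnotationError(f"annotation missing columns: {missing}")
        if t.index.duplicated().any():
            raise AnnotationError("duplicate spot_id in annotation")
        self.validate(strict=False)

    def validate(self, strict: bool = True) -> None:
        """Check field domains and the tumor/non-tumor exclusivity invariants.

        With ``strict`` the nearby sentinel 'unclassified' is disallowed, i.e.
        classify_nearby must have run.
        """
        t = self.table
        bad_tg = ~t["tumor_group"].isin(TUMOR_GROUPS)
        if bad_tg.any():
            raise AnnotationError(f"invalid tumor_group: {t.loc[bad_tg, 'tumor_group'].iloc[0]!r}")
        bad_ng = ~t["nearby_group"].isin(NEARBY_GROUPS)
        if bad_ng.any():
            raise AnnotationError(f"invalid nearby_group: {t.loc[bad_ng, 'nearby_group'].iloc[0]!r}")
        bad_pr = ~t["provenance"].isin(PROVENANCE)
        if bad_pr.any():
            raise AnnotationError(f"invalid provenance: {t.loc[bad_pr, 'provenance'].iloc[0]!r}")
        is_tumor = t["region"] == "tumor"
        if (is_tumor != (t["tumor_group"] != "not_applicable")).any():
            raise AnnotationError("tumor_group must be set exactly on tumor spots")
        if (is_tumor & (t["nearby_group"] != "not_applicable")).any():
            raise AnnotationError("tumor spots cannot carry a nearby_group")
        if strict and (~is_tumor & (t["nearby_group"] == "unclassified")).any():
            raise AnnotationError("non-tumor spots still unclassified; run classify_nearby")

    @property
    def spot_ids(self) -> list[str]:
        return list(self.table.index)

    def spots_where(self, **conditions) -> list[str]:
        """Spot ids matching all given column=value conditions."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.index[mask])

    def copy(self) -> "SpotAnnotation":
        return SpotAnnotation(self.table.copy())

    def to_records(self):
        t = self.table
        return [
            {
                "spot_id": sid,
                "region": row["region"],
                "tumor_group": row["tumor_group"],
                "nearby_group": row["nearby_group"],
                "provenance": row["provenance"],
            }
            for sid, row in t.iterrows()
        ]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpotAnnotation":
        """Build from a TSV-shaped frame with a spot_id column."""
        return cls(df.set_index("spot_id")[list(FIELDS)])


def call_marker_positivity(
    counts: CountMatrix,
    regions,
    marker_gene: str,
    min_count: int = 1,
    other_spots=(),
) -> SpotAnnotation:
    """Assign tumor_group from marker counts.

    Tumor spots listed in ``other_spots`` become 'other' regardless of counts
    (override wins); remaining tumor spots are 'pos' when the marker count is
    >= min_count, else 'neg'. Non-tumor spots get tumor_group not_applicable
    and a pending nearby_group.
    """
    regions = dict(regions)
    missing = [s for s in counts.spot_ids if s not in regions]
    if missing:
        raise AnnotationError(f"regions do not cover all spots, e.g. {missing[:5]}")
    if marker_gene not in counts.gene_ids:
        near = difflib.get_close_matches(marker_gene, counts.gene_ids, n=5)
        raise KeyError(f"marker gene {marker_gene!r} not in matrix; close matches: {near}")
    other = set(other_spots)
    marker = counts.gene_counts(marker_gene)
    rows = {}
    for i, sid in enumerate(counts.spot_ids):
        region = regions[sid]
        if region == "tumor":
            if sid in other:
                tg = "other"
            else:
                tg = "pos" if marker[i] >= min_count else "neg"
            ng = "not_applicable"
        else:
            tg = "not_applicable"
            ng = "unclassified"
        rows[sid] = (region, tg, ng, "automatic")
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(FIELDS)
    )
    table.index.name = "spot_id"
    return SpotAnnotation(table)


def apply_manual_overrides(annotation: SpotAnnotation, overrides) -> tuple[SpotAnnotation, list[dict]]:
    """Apply per-spot field overrides, all-or-nothing, with an audit trail.

    ``overrides`` maps spot_id -> {field: new value}. Changing region across
    the tumor boundary repairs the dependent fields: tumor -> non-tumor sets
    tumor_group to not_applicable and nearby_group to the pending sentinel;
    non-tumor -> tumor requires the override to supply a tumor_group.
    Returns (new annotation, audit records); the input is never mutated.
    """
    table = annotation.table.copy()
    staged: dict[str, dict[str, str]] = {}
    for sid, fields in overrides.items():
        if sid not in table.index:
            raise AnnotationError(f"override for unknown spot {sid!r}")
        unknown = [f for f in fields if f not in FIELDS]
        if unknown:
            raise AnnotationError(f"override for {sid!r} names unknown field(s) {unknown}")
        new = dict(fields)
        old_region = table.at[sid, "region"]
        new_region = new.get("region", old_region)
        if old_region == "tumor" and new_region != "tumor":
            new.setdefault("tumor_group", "not_applicable")
            new.setdefault("nearby_group", "unclassified")
        if old_region != "tumor" and new_region == "tumor":
            if new.get("tumor_group", "not_applicable") == "not_applicable":
                raise AnnotationError(
                    f"override makes {sid!r} tumor but supplies no tumor_group"
                )
            new.setdefault("nearby_group", "not_applicable")
        staged[sid] = new

    audit: list[dict] = []
    for sid, new in staged.items():
        for f, v in new.items():
            old = table.at[sid, f]
            if old != v:
                audit.append({"spot_id": sid, "field": f, "old": old, "new": v})
            table.at[sid, f] = v
        if new:
            table.at[sid, "provenance"] = "manual"
    result = SpotAnnotation(table)  # validates; raises before returning on violation
    return result, audit
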