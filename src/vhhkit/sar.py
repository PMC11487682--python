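"""Structure-activity relationship analysis over affinity tables.

Consumes a variant affinity table (KD in nM, kinetic constants, yield and
SEC purity, with ``nb`` marking non-binders) and the variants' mutation
sets relative to a common parental sequence, and derives:

* KD fold changes versus a reference (reported at 1 decimal alongside
  full precision, matching how such campaigns are discussed);
* a relevance call -- given the noise of biolayer interferometry and
  batch-to-batch variability, only an affinity reduction *above* a factor
  of 2 counts as relevant;
* matched molecular pairs (MMPs): variant pairs whose mutation sets differ
  by exactly one substitution, isolating that substitution's effect;
* per-mutation effect aggregation: the geometric mean and range of MMP
  fold changes (fold effects are multiplicative), with non-binder
  outcomes tallied separately as qualitative knockouts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import DuplicateVariantId, ParseError

NON_BINDER_TOKENS = {"nb", "n.b.", "nonbinder", "non-binder"}


@dataclass(frozen=True)
class AffinityRecord:
    """One row of a variant affinity table; ``kd`` is None for non-binders."""

    variant_id: str
    kd: float | None            # nM
    kon: float | None = None    # 1/(M s)
    koff: float | None = None   # 1/s
    emax: float | None = None   # nm
    r2: float | None = None
    yield_mg_l: float | None = None
    sec_purity: float | None = None

    @property
    def is_binder(self) -> bool:
        return self.kd is not None


_COLUMN_ALIASES = {
    "variant_id": {"variant_id", "variant", "id", "name"},
    "kd": {"kd", "kd_nm", "kd (nm)"},
    "kon": {"kon", "k_on", "kon (1/ms)"},
    "koff": {"koff", "k_off", "koff (1/s)"},
    "emax": {"emax", "emax_nm", "emax_100nm"},
    "r2": {"r2", "r^2"},
    "yield_mg_l": {"yield", "yield_mg_l", "yield_mg_per_l", "yield (mg/l)"},
    "sec_purity": {"sec_purity", "sec_purity_pct", "purity", "sec purity (%)"},
}


def _canonical_columns(columns) -> dict:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        for canon, aliases in _COLUMN_ALIASES.items():
            if key in aliases:
                mapping[col] = canon
    return mapping


def read_affinity_table(path) -> list[AffinityRecord]:
    """Read a CSV/TSV affinity table; ``nb`` parses as a non-binder flag."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and len(df.columns) <= 1:
        return []
    mapping = _canonical_columns(df.columns)
    if "variant_id" not in mapping.values() or "kd" not in mapping.values():
        raise ParseError(f"{path}: need at least variant and KD columns")
    df = df.rename(columns=mapping)
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        vid = str(row["variant_id"]).strip()
        kwargs = {"variant_id": vid}
        kd_raw = str(row["kd"]).strip().lower()
        nonbinder = kd_raw in NON_BINDER_TOKENS
        for field in ("kd", "kon", "koff", "emax", "r2", "yield_mg_l", "sec_purity"):
            raw = row.get(field)
            if raw is None or str(raw).strip() == "" or str(raw).strip().lower() == "nan":
                kwargs[field] = None
                continue
            raw = str(raw).strip()
            if raw.lower() in NON_BINDER_TOKENS:
                kwargs[field] = None
                continue
            try:
                kwargs[field] = float(raw)
            except ValueError:
                raise ParseError(f"cannot parse {field}={raw!r}", row=i) from None
        if not nonbinder and kwargs["kd"] is not None and kwargs["kd"] <= 0:
            raise ParseError(f"KD must be positive, got {kwargs['kd']}", row=i)
        records.append(AffinityRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# fold changes


@dataclass(frozen=True)
class FoldChange:
    variant_id: str
    reference_id: str
    value: float                 # kd(variant) / kd(reference); inf for knockouts
    nonbinder: bool = False

    @property
    def rounded(self) -> float:
        return round(self.value, 1)

    @property
    def relevant(self) -> bool:
        return classify_relevant(self.value)


def fold_change(variant: AffinityRecord, reference: AffinityRecord) -> FoldChange:
    """KD ratio variant/reference; a non-binder variant yields a flagged inf."""
    if not reference.is_binder:
        raise ParseError(f"reference {reference.variant_id} is a non-binder")
    if not variant.is_binder:
        return FoldChange(variant.variant_id, reference.variant_id, math.inf, nonbinder=True)
    return FoldChange(variant.variant_id, reference.variant_id, variant.kd / reference.kd)


def classify_relevant(ratio: float) -> bool:
    """Affinity reduction above a factor of 2 (strictly) is relevant."""
    if ratio <= 0:
        raise ValueError("fold-change ratio must be positive")
    return ratio > 2.0


# ---------------------------------------------------------------------------
# matched molecular pairs


@dataclass(frozen=True)
class MatchedMolecularPair:
    """Two variants differing by exactly one mutation; reference lacks it."""

    reference_id: str
    variant_id: str
    mutation: str


def find_mmps(variants) -> list:
    """All matched molecular pairs among ``(id, mutation set)`` entries.

    Pairs are unordered but reported reference-first (the member lacking
    the differing mutation).  Mutation sets are relative to one common
    parental sequence.
    """
    items = [(vid, frozenset(muts)) for vid, muts in variants]
    ids = [vid for vid, _ in items]
    if len(ids) != len(set(ids)):
        raise DuplicateVariantId("variant ids must be unique")
    mmps = []
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            (id_a, set_a), (id_b, set_b) = items[i], items[j]
            diff = set_a ^ set_b
            if len(diff) != 1:
                continue
            (mutation,) = diff
            if mutation in set_b:
                mmps.append(MatchedMolecularPair(id_a, id_b, mutation))
            else:
                mmps.append(MatchedMolecularPair(id_b, id_a, mutation))
    return mmps


def per_mutation_effect(mmps, affinities) -> pd.DataFrame:
    """Aggregate MMP fold changes per mutation.

    Returns a table with the geometric mean and range of KD fold changes
    across all MMPs probing each mutation; pairs whose mutated member is a
    non-binder are counted as knockouts and excluded from the mean.
    """
    if not isinstance(affinities, dict):
        affinities = {rec.variant_id: rec for rec in affinities}
    rows: dict[str, dict] = {}
    for mmp in mmps:
        ref = affinities.get(mmp.reference_id)
        var = affinities.get(mmp.variant_id)
        if ref is None or var is None or not ref.is_binder:
            continue
        entry = rows.setdefault(
            mmp.mutation, {"ratios": [], "knockouts": 0, "pairs": []}
        )
        if not var.is_binder:
            entry["knockouts"] += 1
            entry["pairs"].append((mmp.reference_id, mmp.variant_id, math.inf))
            continue
        ratio = var.kd / ref.kd
        entry["ratios"].append(ratio)
        entry["pairs"].append((mmp.reference_id, mmp.variant_id, ratio))
    out = []
    for mutation in sorted(rows):
        entry = rows[mutation]
        ratios = entry["ratios"]
        if ratios:
            gmean = math.exp(sum(math.log(r) for r in ratios) / len(ratios))
            lo, hi = min(ratios), max(ratios)
        else:
            gmean = lo = hi = math.nan
        out.append(
            {
                "mutation": mutation,
                "n_pairs": len(ratios),
                "geometric_mean": gmean,
                "min": lo,
                "max": hi,
                "knockouts": entry["knockouts"],
            }
        )
    return pd.DataFrame(out, columns=["mutation", "n_pairs", "geometric_mean", "min", "max", "knockouts"])


# ---------------------------------------------------------------------------
# bundled example dataset


def read_variant_mutations(path) -> list:
    """Read ``variant_id,mutations`` CSV (mutations ';'-separated)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        muts = frozenset(m for m in str(row["mutations"]).split(";") if m)
        out.append((row["variant_id"].strip(), muts))
    return out


def load_example_affinity_table() -> list[AffinityRecord]:
    """Bundled affinity table for the VHH1/VHH2 humanization series."""
    with resources.as_file(resources.files("vhhkit.data") / "vhh_affinity_table.csv") as p:
        return read_affinity_table(p)


def load_example_variant_mutations() -> list:
    """Bundled (reconstructed) mutation sets for the VHH1/VHH2 series."""
    with resources.as_file(
        resources.files("vhhkit.data") / "variant_mutations_reconstructed.csv"
    ) as p:
        return read_variant_mutations(p)


@dataclass
class SARReport:
    reference_id: str
    fold_changes: list           # FoldChange vs reference
    mmps: list                   # MatchedMolecularPair
    effects: pd.DataFrame        # per-mutation aggregation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variant_id": fc.variant_id,
                    "reference_id": fc.reference_id,
                    "fold_change": fc.value,
                    "fold_change_1dp": fc.rounded,
                    "nonbinder": fc.nonbinder,
                    "relevant": (fc.relevant if math.isfinite(fc.value) else True),
                }
                for fc in self.fold_changes
            ]
        )


def sar_report(records, variant_mutations, reference_id: str) -> SARReport:
    """Fold changes vs the reference, MMPs and per-mutation effects."""
    affinities = {rec.variant_id: rec for rec in records}
    if reference_id not in affinities:
        raise ParseError(f"reference {reference_id!r} not in affinity table")
    ref = affinities[reference_id]
    fcs = [
        fold_change(rec, ref)
        for rec in records
        if rec.variant_id != reference_id
    ]
    known = [(vid, muts) for vid, muts in variant_mutations if vid in affinities]
    mmps = find_mmps(known)
    effects = per_mutation_effect(mmps, affinities)
    return SARReport(reference_id, fcs, mmps, effects)
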