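"""Training-data construction from SKEMPI-style affinity tables.

Binding free energies come from dissociation constants via
dG = R T ln(KD) with R = 1.985e-3 kcal K^-1 mol^-1, and the effect of a
mutation is ddG = dG_wild-type - dG_mutant (note: many resources use the
opposite sign; this package keeps the wt - mt convention throughout).
Replicated measurements are averaged when their spread is below
2.0 kcal/mol and discarded otherwise; only single-point mutations are
retained. Because ddG is a state function, each mutation implies a
hypothetical reverse mutation with the negated ddG; augmenting with
these balances the dataset and enforces antisymmetry. Three split
generators support the validation protocols: paired stratified k-fold
(forward/reverse twins never straddle folds), leave-one-complex-out and
leave-one-binding-site-out.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

#: ideal gas constant, kcal K^-1 mol^-1
R_GAS = 1.985e-3
#: default experiment temperature, K
DEFAULT_TEMPERATURE = 298.15

#: replicate measurements may spread less than this (kcal/mol)
REPLICATE_TOLERANCE = 2.0

DISCARDED = object()     # marker returned for over-dispersed replicates


@dataclass(frozen=True)
class MutationRecord:
    pdb_id: str
    chain: str
    res_number: int
    wt_aa: str
    mut_aa: str
    ddg: float                      # kcal/mol, wt - mt convention
    icode: str = ""
    kd_wt: float | None = None
    kd_mut: float | None = None
    temperature: float = DEFAULT_TEMPERATURE
    complex_id: str = ""
    binding_site_id: str = ""
    is_reverse: bool = False
    forward_key: str = ""           # link to the forward twin (reverse records)
    source_row: int = -1

    @property
    def key(self) -> str:
        tag = "rev" if self.is_reverse else "fwd"
        return (f"{self.pdb_id}_{self.chain}_{self.wt_aa}{self.res_number}"
                f"{self.icode}{self.mut_aa}_{tag}")


@dataclass
class SplitPlan:
    scheme: str                     # stratified_kfold_paired | loco | lobso
    assignments: dict[str, int]     # record key -> fold / test-group index
    n_groups: int
    seed: int | None = None
    repeat_assignments: list[dict[str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# thermodynamics


def dg_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy dG = R T ln(KD), kcal/mol (KD in molar)."""
    if kd <= 0:
        raise ValueError(f"KD must be positive, got {kd}")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_GAS * temperature * math.log(kd)


def ddg(dg_wt: float, dg_mut: float) -> float:
    """Change in binding affinity upon mutation, dG_wild-type - dG_mutant."""
    if not (math.isfinite(dg_wt) and math.isfinite(dg_mut)):
        raise ValueError("free energies must be finite")
    return dg_wt - dg_mut


def aggregate_replicates(values: list[float],
                         tol: float = REPLICATE_TOLERANCE):
    """Mean of replicate ddG measurements, or a discard marker.

    Replicates are kept when max - min is strictly below ``tol``
    (2.0 kcal/mol by default) and discarded otherwise.
    """
    if not values:
        raise ValueError("no replicate values")
    if max(values) - min(values) < tol:
        return float(np.mean(values))
    return DISCARDED


# ---------------------------------------------------------------------------
# SKEMPI 2.0 dialect parsing


_MUT_RE = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([a-z]?)([A-Z])$")

REQUIRED_COLUMNS = ("#Pdb", "Mutation(s)_cleaned", "Affinity_wt_parsed",
                    "Affinity_mut_parsed")


def _parse_mutation(token: str):
    """'LI38G' -> (wt='L', chain='I', number=38, icode='', mut='G')."""
    m = _MUT_RE.match(token.strip())
    if not m:
        raise ValueError(f"cannot parse mutation '{token}'")
    wt, chain, num, icode, mut = m.groups()
    return wt, chain, int(num), icode, mut


def parse_skempi(path, tol: float = REPLICATE_TOLERANCE,
                 default_temperature: float = DEFAULT_TEMPERATURE
                 ) -> list[MutationRecord]:
    """Curate a SKEMPI 2.0 style table (semicolon-separated) into records.

    Keeps single-point mutations with parseable wild-type and mutant
    affinities; converts each row to ddG at its recorded temperature
    (default 298.15 K when missing); aggregates replicates of the same
    variant and discards over-dispersed ones. Deterministic and
    order-independent.
    """
    df = pd.read_csv(path, sep=";")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SKEMPI table missing mandatory columns: {missing}")

    groups: dict[tuple, list] = {}
    n_multi = n_bad_affinity = 0
    for idx, row in df.iterrows():
        mut_field = str(row["Mutation(s)_cleaned"]).strip()
        if "," in mut_field:
            n_multi += 1
            continue
        try:
            wt, chain, num, icode, mut = _parse_mutation(mut_field)
        except ValueError:
            n_multi += 1
            continue
        try:
            kd_wt = float(row["Affinity_wt_parsed"])
            kd_mut = float(row["Affinity_mut_parsed"])
            if not (kd_wt > 0 and kd_mut > 0):
                raise ValueError
        except (TypeError, ValueError):
            n_bad_affinity += 1
            continue
        temp = default_temperature
        if "Temperature" in df.columns and not pd.isna(row["Temperature"]):
            # SKEMPI temperature cells may carry annotations, e.g. "298(assumed)"
            m = re.search(r"\d+(\.\d+)?", str(row["Temperature"]))
            if m:
                temp = float(m.group())
        pdb_id = str(row["#Pdb"]).split("_")[0].strip()
        key = (pdb_id, chain, num, icode, wt, mut)
        value = ddg(dg_from_kd(kd_wt, temp), dg_from_kd(kd_mut, temp))
        groups.setdefault(key, []).append((value, kd_wt, kd_mut, temp, int(idx)))

    records, n_discarded = [], 0
    for key in sorted(groups):
        pdb_id, chain, num, icode, wt, mut = key
        entries = groups[key]
        agg = aggregate_replicates([e[0] for e in entries], tol)
        if agg is DISCARDED:
            n_discarded += 1
            continue
        _, kd_wt, kd_mut, temp, src = entries[0]
        records.append(MutationRecord(
            pdb_id=pdb_id, chain=chain, res_number=num, icode=icode,
            wt_aa=wt, mut_aa=mut, ddg=agg, kd_wt=kd_wt, kd_mut=kd_mut,
            temperature=temp, complex_id=pdb_id,
            binding_site_id=f"{pdb_id}_{chain}_{num}{icode}", source_row=src))
    logger.info("parse_skempi: %d retained, %d multi-point/unparseable "
                "dropped, %d bad-affinity rows skipped, %d over-dispersed "
                "variants discarded", len(records), n_multi, n_bad_affinity,
                n_discarded)
    return records


def curation_counts(path, **kwargs) -> dict[str, int]:
    """Filter-stage bookkeeping for a SKEMPI-style table."""
    records = parse_skempi(path, **kwargs)
    return {
        "retained": len(records),
        "complexes": len({r.complex_id for r in records}),
        "increased": sum(1 for r in records if r.ddg >= 0),
        "decreased": sum(1 for r in records if r.ddg < 0),
    }


# ---------------------------------------------------------------------------
# antisymmetric augmentation


def augment_reverse(records: list[MutationRecord]) -> list[MutationRecord]:
    """Append the hypothetical reverse mutation of every forward record.

    Each reverse twin swaps wild-type and mutant, negates ddG, and keeps
    a link to its forward counterpart. Raises on already-augmented input
    (augmentation is not idempotent).
    """
    if any(r.is_reverse for r in records):
        raise ValueError("records already contain reverse mutations")
    out = list(records)
    for r in records:
        out.append(replace(
            r, wt_aa=r.mut_aa, mut_aa=r.wt_aa, ddg=-r.ddg,
            kd_wt=r.kd_mut, kd_mut=r.kd_wt,
            is_reverse=True, forward_key=r.key))
    return out


# ---------------------------------------------------------------------------
# split generators


def split_stratified_paired(records: list[MutationRecord], k: int = 10,
                            repeats: int = 10, seed: int = 0) -> SplitPlan:
    """Repeated stratified k-fold keeping forward/reverse twins together.

    Folds are drawn over the forward records, stratified on the sign of
    the forward ddG (ddG >= 0 counts as increased affinity); each reverse
    twin inherits its forward record's fold. The first repeat populates
    ``assignments``; all repeats are kept in ``repeat_assignments``.
    """
    forward = [r for r in records if not r.is_reverse]
    if k > len(forward):
        raise ValueError(f"k={k} exceeds number of forward records "
                         f"({len(forward)})")
    reverse_by_fwd: dict[str, list[MutationRecord]] = {}
    for r in records:
        if r.is_reverse:
            reverse_by_fwd.setdefault(r.forward_key, []).append(r)
    labels = np.array([int(r.ddg >= 0) for r in forward])
    all_repeats = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + rep)
        assign: dict[str, int] = {}
        for fold, (_, test_idx) in enumerate(
                skf.split(np.zeros(len(forward)), labels)):
            for i in test_idx:
                fwd = forward[i]
                assign[fwd.key] = fold
                for twin in reverse_by_fwd.get(fwd.key, []):
                    assign[twin.key] = fold
        all_repeats.append(assign)
    return SplitPlan(scheme="stratified_kfold_paired",
                     assignments=all_repeats[0], n_groups=k, seed=seed,
                     repeat_assignments=all_repeats)


def split_leave_one_complex_out(records: list[MutationRecord]) -> SplitPlan:
    """One test group per complex; train/test never share a complex."""
    complexes = sorted({r.complex_id for r in records})
    if len(complexes) < 2:
        raise ValueError("leave-one-complex-out needs at least two complexes")
    index = {c: i for i, c in enumerate(complexes)}
    assign = {r.key: index[r.complex_id] for r in records}
    return SplitPlan(scheme="loco", assignments=assign,
                     n_groups=len(complexes))


def split_leave_one_binding_site_out(records: list[MutationRecord]) -> SplitPlan:
    """One test group per binding site (pdb + chain + position fallback)."""
    sites = sorted({r.binding_site_id for r in records})
    if len(sites) < 2:
        raise ValueError("leave-one-binding-site-out needs at least two sites")
    if any(not r.binding_site_id for r in records):
        raise ValueError("records lack binding_site_id")
    index = {sid: i for i, sid in enumerate(sites)}
    assign = {r.key: index[r.binding_site_id] for r in records}
    return SplitPlan(scheme="lobso", assignments=assign, n_groups=len(sites))


def records_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    """Curated dataset as a DataFrame with provenance columns."""
    return pd.DataFrame([{
        "pdb_id": r.pdb_id, "chain": r.chain, "res_number": r.res_number,
        "icode": r.icode, "wt_aa": r.wt_aa, "mut_aa": r.mut_aa,
        "ddg": r.ddg, "temperature": r.temperature,
        "complex_id": r.complex_id, "binding_site_id": r.binding_site_id,
        "is_reverse": r.is_reverse, "forward_key": r.forward_key,
        "source_row": r.source_row,
    } for r in records])
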