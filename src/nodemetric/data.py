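"""Domain types, cohort-table I/O, and analysis-set construction.

The analysis unit throughout is a single lymph node measured by a single
reader. A cohort table is a long-format CSV with one row per node x reader;
per-patient reference measurements (up to three contralateral benign nodes
and one muscle region per DWI sequence) are carried as wide columns on each
row and de-duplicated into :class:`ReferencePanel` objects on read.

Two node-level analysis sets are built from a cohort:

* the sentinel set (``SLN_SET``): all sentinel nodes, minus every benign
  node belonging to a patient who also has at least one metastatic node
  (those are excluded to avoid binding effects between a patient's nodes);
* the pooled metastatic set (``MLN_SET``): all confirmed metastatic nodes of
  the advanced-stage group plus all benign sentinel nodes, including the
  benign nodes the sentinel set excluded.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "Sequence",
    "CohortGroup",
    "Basin",
    "TruthStatus",
    "Reader",
    "LymphNodeRecord",
    "ReferencePanel",
    "AnalysisSet",
    "CohortTable",
    "SchemaError",
    "ValidationError",
    "SCHEMA_VERSION",
    "SCHEMA_COLUMNS",
    "METRICS",
    "read_cohort_table",
    "write_cohort_table",
    "build_sln_set",
    "build_mln_set",
    "metric_values",
    "records_to_frame",
    "pivot_readers",
]


class SchemaError(ValueError):
    """Cohort file header does not match the documented schema."""


class ValidationError(ValueError):
    """A row violates a type invariant (carries the offending row index)."""


class Sequence(str, enum.Enum):
    EPI = "EPI"
    RESOLVE = "RESOLVE"
    VOL = "VOL"


#: column-name suffix per DWI sequence
SEQ_SUFFIX = {Sequence.EPI: "epi", Sequence.RESOLVE: "res", Sequence.VOL: "vol"}


class CohortGroup(str, enum.Enum):
    SLN = "SLN"
    MLN = "MLN"


class Basin(str, enum.Enum):
    AXILLARY = "axillary"
    CERVICAL = "cervical"
    INGUINAL = "inguinal"
    ILIACAL = "iliacal"
    MESENTERIAL = "mesenterial"


class TruthStatus(str, enum.Enum):
    METASTATIC = "metastatic"
    BENIGN = "benign"


class Reader(str, enum.Enum):
    R1 = "R1"
    R2 = "R2"


SCHEMA_VERSION = "1.0"

#: documented column list of the cohort CSV (comma-separated, UTF-8, header
#: row, decimal point, empty string = absent value); all columns mandatory
#: in the header, measurement values may be empty.
SCHEMA_COLUMNS = (
    "patient_id",
    "node_id",
    "cohort_group",
    "basin",
    "truth_status",
    "reader",
    "adc_epi",
    "adc_res",
    "adc_vol",
    "roi_epi_voxels",
    "roi_res_voxels",
    "voi_mm3",
    "sad_mm",
    "node_rads",
    "contralateral_adc_1_epi",
    "contralateral_adc_2_epi",
    "contralateral_adc_3_epi",
    "contralateral_adc_1_res",
    "contralateral_adc_2_res",
    "contralateral_adc_3_res",
    "contralateral_adc_1_vol",
    "contralateral_adc_2_vol",
    "contralateral_adc_3_vol",
    "muscle_adc_epi",
    "muscle_adc_res",
    "muscle_adc_vol",
)

#: metric identifier -> (kind, sequence); orientation lives in diag_perf.
METRICS = {
    "adc_epi": ("adc", Sequence.EPI),
    "adc_res": ("adc", Sequence.RESOLVE),
    "adc_vol": ("adc", Sequence.VOL),
    "cadc_epi": ("cadc", Sequence.EPI),
    "cadc_res": ("cadc", Sequence.RESOLVE),
    "cadc_vol": ("cadc", Sequence.VOL),
    "madc_epi": ("madc", Sequence.EPI),
    "madc_res": ("madc", Sequence.RESOLVE),
    "madc_vol": ("madc", Sequence.VOL),
    "sad": ("sad", None),
    "node_rads": ("node_rads", None),
}


@dataclass
class LymphNodeRecord:
    """One lymph node as measured by one reader across all sequences.

    ADC values are in 10^-6 mm^2/s; any per-sequence entry may be absent.
    ``ratios`` is filled by :func:`nodemetric.ratios.annotate_ratios`.
    """

    patient_id: str
    node_id: str
    cohort_group: CohortGroup
    basin: Basin
    truth_status: TruthStatus
    reader: Reader
    adc: dict[Sequence, float] = field(default_factory=dict)
    roi_voxels: dict[Sequence, int] = field(default_factory=dict)
    voi_mm3: float | None = None
    sad_mm: float | None = None
    node_rads: int | None = None
    ratios: "object | None" = None  # RatioSet, attached downstream

    def validate(self, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        for seq, v in self.adc.items():
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(
                    f"non-positive ADC {v!r} for sequence {seq.value}{where}"
                )
        for seq, n in self.roi_voxels.items():
            if n < 2:
                raise ValidationError(
                    f"ROI must cover more than one voxel, got {n}{where}"
                )
        if self.sad_mm is not None and not self.sad_mm > 0:
            raise ValidationError(f"non-positive short-axis diameter{where}")
        if self.node_rads is not None and self.node_rads not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"Node-RADS must be an integer 1-5, got {self.node_rads!r}{where}"
            )
        if self.voi_mm3 is not None and not self.voi_mm3 > 0:
            raise ValidationError(f"non-positive VOI volume{where}")

    @property
    def key(self) -> tuple[str, str]:
        """Node identity, reader-independent."""
        return (self.patient_id, self.node_id)


@dataclass
class ReferencePanel:
    """Per patient x reader reference ADCs: up to three contralateral benign
    nodes and one fixed muscle region, per sequence (10^-6 mm^2/s)."""

    patient_id: str
    reader: Reader
    contralateral_adc: dict[Sequence, list[float]] = field(default_factory=dict)
    muscle_adc: dict[Sequence, float] = field(default_factory=dict)

    def validate(self, row: int | None = None) -> None:
        where = "" if row is None else f" (row {row})"
        for seq, vals in self.contralateral_adc.items():
            if len(vals) > 3:
                raise ValidationError(
                    f"more than 3 contralateral values for {seq.value}{where}"
                )
            for v in vals:
                if not v > 0:
                    raise ValidationError(
                        f"non-positive contralateral ADC {v!r}{where}"
                    )
        for seq, v in self.muscle_adc.items():
            if not v > 0:
                raise ValidationError(f"non-positive muscle ADC {v!r}{where}")


class SetName(str, enum.Enum):
    SLN_SET = "SLN_SET"
    MLN_SET = "MLN_SET"
    ALL_LNS = "ALL_LNS"


@dataclass
class AnalysisSet:
    """A node-based analysis dataset with its construction provenance.

    ``records`` holds every reader's rows for the included nodes; node
    counts (``n_nodes``, ``n_pos``, ``n_neg``) are over unique nodes.
    """

    name: SetName
    records: list[LymphNodeRecord]
    provenance_log: list[str] = field(default_factory=list)

    def reader_records(self, reader: Reader) -> list[LymphNodeRecord]:
        return [r for r in self.records if r.reader == reader]

    @property
    def node_keys(self) -> set[tuple[str, str]]:
        return {r.key for r in self.records}

    def _node_truth(self) -> dict[tuple[str, str], TruthStatus]:
        return {r.key: r.truth_status for r in self.records}

    @property
    def n_nodes(self) -> int:
        return len(self.node_keys)

    @property
    def n_pos(self) -> int:
        return sum(
            1 for t in self._node_truth().values() if t is TruthStatus.METASTATIC
        )

    @property
    def n_neg(self) -> int:
        return sum(1 for t in self._node_truth().values() if t is TruthStatus.BENIGN)


@dataclass
class CohortTable:
    """Validated result of :func:`read_cohort_table`."""

    records: list[LymphNodeRecord]
    panels: list[ReferencePanel]
    diagnostics: list[str] = field(default_factory=list)

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.records, self.panels))


def _parse_float(token, col: str, row: int) -> float | None:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return None
    s = str(token).strip()
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise ValidationError(f"unparseable number {s!r} in column {col} (row {row})")


def _parse_enum(enum_cls, token, col: str, row: int):
    s = str(token).strip()
    try:
        return enum_cls(s)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ValidationError(
            f"unknown {col} token {s!r} (row {row}); expected one of: {valid}"
        )


def read_cohort_table(path, schema_version: str = SCHEMA_VERSION) -> CohortTable:
    """Read and validate a long-format cohort CSV.

    Returns a :class:`CohortTable` of validated records and de-duplicated
    reference panels. Raises :class:`SchemaError` when a mandatory column is
    missing and :class:`ValidationError` (naming the row) when a value
    violates a type invariant. Soft issues (fewer than three contralateral
    references, absent panels) are reported in ``diagnostics``.
    """
    if schema_version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {schema_version!r}; this reader "
            f"implements {SCHEMA_VERSION!r}"
        )
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[LymphNodeRecord] = []
    panels: dict[tuple[str, Reader], ReferencePanel] = {}
    diagnostics: list[str] = []
    seen_rows: set[tuple[str, str, Reader]] = set()

    for i, row in enumerate(df.to_dict("records")):
        pid = str(row["patient_id"]).strip()
        nid = str(row["node_id"]).strip()
        if not pid or not nid:
            raise ValidationError(f"empty patient_id/node_id (row {i})")
        reader = _parse_enum(Reader, row["reader"], "reader", i)
        key = (pid, nid, reader)
        if key in seen_rows:
            raise ValidationError(
                f"duplicate row for node {nid} of patient {pid}, reader "
                f"{reader.value} (row {i})"
            )
        seen_rows.add(key)

        adc, roi = {}, {}
        for seq, sfx in SEQ_SUFFIX.items():
            v = _parse_float(row[f"adc_{sfx}"], f"adc_{sfx}", i)
            if v is not None:
                adc[seq] = v
        for seq, sfx in ((Sequence.EPI, "epi"), (Sequence.RESOLVE, "res")):
            v = _parse_float(row[f"roi_{sfx}_voxels"], f"roi_{sfx}_voxels", i)
            if v is not None:
                roi[seq] = int(v)
        nr = _parse_float(row["node_rads"], "node_rads", i)
        rec = LymphNodeRecord(
            patient_id=pid,
            node_id=nid,
            cohort_group=_parse_enum(CohortGroup, row["cohort_group"], "cohort_group", i),
            basin=_parse_enum(Basin, row["basin"], "basin", i),
            truth_status=_parse_enum(TruthStatus, row["truth_status"], "truth_status", i),
            reader=reader,
            adc=adc,
            roi_voxels=roi,
            voi_mm3=_parse_float(row["voi_mm3"], "voi_mm3", i),
            sad_mm=_parse_float(row["sad_mm"], "sad_mm", i),
            node_rads=None if nr is None else int(nr),
        )
        rec.validate(row=i)
        records.append(rec)

        contra: dict[Sequence, list[float]] = {}
        muscle: dict[Sequence, float] = {}
        for seq, sfx in SEQ_SUFFIX.items():
            vals = [
                v
                for k in (1, 2, 3)
                if (
                    v := _parse_float(
                        row[f"contralateral_adc_{k}_{sfx}"],
                        f"contralateral_adc_{k}_{sfx}",
                        i,
                    )
                )
                is not None
            ]
            if vals:
                contra[seq] = vals
            m = _parse_float(row[f"muscle_adc_{sfx}"], f"muscle_adc_{sfx}", i)
            if m is not None:
                muscle[seq] = m
        if contra or muscle:
            panel = ReferencePanel(pid, reader, contra, muscle)
            panel.validate(row=i)
            prev = panels.get((pid, reader))
            if prev is None:
                panels[(pid, reader)] = panel
            elif (prev.contralateral_adc, prev.muscle_adc) != (contra, muscle):
                raise ValidationError(
                    f"conflicting reference panel for patient {pid}, reader "
                    f"{reader.value} (row {i})"
                )
            for seq, vals in contra.items():
                if len(vals) < 3:
                    msg = (
                        f"patient {pid} reader {reader.value}: only {len(vals)} "
                        f"contralateral value(s) for {seq.value}"
                    )
                    if msg not in diagnostics:
                        diagnostics.append(msg)

    return CohortTable(records, list(panels.values()), diagnostics)


def write_cohort_table(records, panels, path) -> None:
    """Write records + panels back to the documented CSV schema (lossless)."""
    panel_map = {(p.patient_id, p.reader): p for p in panels}
    rows = []
    for rec in records:
        row = {c: "" for c in SCHEMA_COLUMNS}
        row.update(
            patient_id=rec.patient_id,
            node_id=rec.node_id,
            cohort_group=rec.cohort_group.value,
            basin=rec.basin.value,
            truth_status=rec.truth_status.value,
            reader=rec.reader.value,
        )
        for seq, sfx in SEQ_SUFFIX.items():
            if seq in rec.adc:
                row[f"adc_{sfx}"] = repr(rec.adc[seq])
        for seq, sfx in ((Sequence.EPI, "epi"), (Sequence.RESOLVE, "res")):
            if seq in rec.roi_voxels:
                row[f"roi_{sfx}_voxels"] = str(rec.roi_voxels[seq])
        if rec.voi_mm3 is not None:
            row["voi_mm3"] = repr(rec.voi_mm3)
        if rec.sad_mm is not None:
            row["sad_mm"] = repr(rec.sad_mm)
        if rec.node_rads is not None:
            row["node_rads"] = str(rec.node_rads)
        panel = panel_map.get((rec.patient_id, rec.reader))
        if panel is not None:
            for seq, sfx in SEQ_SUFFIX.items():
                for k, v in enumerate(panel.contralateral_adc.get(seq, []), start=1):
                    row[f"contralateral_adc_{k}_{sfx}"] = repr(v)
                if seq in panel.muscle_adc:
                    row[f"muscle_adc_{sfx}"] = repr(panel.muscle_adc[seq])
        rows.append(row)
    pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analysis-set construction
# ---------------------------------------------------------------------------


def _node_truth_map(records) -> dict[tuple[str, str], TruthStatus]:
    truth: dict[tuple[str, str], TruthStatus] = {}
    for r in records:
        prev = truth.get(r.key)
        if prev is not None and prev is not r.truth_status:
            raise ValidationError(
                f"inconsistent truth status across readers for node "
                f"{r.node_id} of patient {r.patient_id}"
            )
        truth[r.key] = r.truth_status
    return truth


def build_sln_set(records) -> AnalysisSet:
    """Construct the sentinel-node analysis set.

    Within the sentinel cohort, every benign node of a patient who also has
    at least one metastatic node is excluded (to avoid binding effects);
    each exclusion is logged in ``provenance_log``.
    """
    sln = [r for r in records if r.cohort_group is CohortGroup.SLN]
    if not sln:
        raise ValueError("no sentinel-cohort records in input")
    truth = _node_truth_map(sln)
    pos_patients = {
        pid for (pid, _), t in truth.items() if t is TruthStatus.METASTATIC
    }
    log = []
    kept, excluded_keys = [], set()
    for (pid, nid), t in truth.items():
        if t is TruthStatus.BENIGN and pid in pos_patients:
            excluded_keys.add((pid, nid))
            log.append(
                f"excluded benign node {nid} of patient {pid}: patient has "
                f"at least one metastatic sentinel node"
            )
    kept = [r for r in sln if r.key not in excluded_keys]
    aset = AnalysisSet(SetName.SLN_SET, kept, log)
    log.append(
        f"sentinel set: {aset.n_nodes} nodes ({aset.n_pos} metastatic, "
        f"{aset.n_neg} benign); {len(excluded_keys)} benign node(s) excluded"
    )
    return aset


def n_exclusions(aset: AnalysisSet) -> int:
    """Number of nodes excluded during set construction (from the log)."""
    return sum(1 for line in aset.provenance_log if line.startswith("excluded"))


def build_mln_set(records) -> AnalysisSet:
    """Construct the pooled metastatic analysis set.

    Positives are every metastatic node of the advanced-stage (MLN) cohort;
    negatives are every benign sentinel node, including those the sentinel
    set excluded. Benign MLN-cohort nodes are excluded and logged.
    """
    truth = _node_truth_map(records)
    group = {r.key: r.cohort_group for r in records}
    log = []
    keep = set()
    for key, t in truth.items():
        g = group[key]
        if g is CohortGroup.MLN:
            if t is TruthStatus.METASTATIC:
                keep.add(key)
            else:
                log.append(
                    f"excluded benign node {key[1]} of patient {key[0]}: "
                    f"benign nodes of the MLN cohort are not part of this set"
                )
        elif t is TruthStatus.BENIGN:
            keep.add(key)
    kept = [r for r in records if r.key in keep]
    aset = AnalysisSet(SetName.MLN_SET, kept, log)
    if aset.n_pos == 0:
        log.append("WARNING: pooled set has zero metastatic nodes")
    log.append(
        f"pooled set: {aset.n_nodes} nodes ({aset.n_pos} metastatic, "
        f"{aset.n_neg} benign)"
    )
    return aset


# ---------------------------------------------------------------------------
# tabular views
# ---------------------------------------------------------------------------


def metric_values(record: LymphNodeRecord, metric: str) -> float | None:
    """Value of a named metric for one record, or ``None`` when absent.

    Ratio metrics require :func:`nodemetric.ratios.annotate_ratios` to have
    run first.
    """
    kind, seq = METRICS[metric]
    if kind == "adc":
        return record.adc.get(seq)
    if kind == "sad":
        return record.sad_mm
    if kind == "node_rads":
        return None if record.node_rads is None else float(record.node_rads)
    if record.ratios is None:
        return None
    if kind == "cadc":
        return record.ratios.cadc.get(seq)
    return record.ratios.madc.get(seq)


def records_to_frame(records) -> pd.DataFrame:
    """Flat per-row view of records with one column per metric identifier."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "node_id": r.node_id,
            "cohort_group": r.cohort_group.value,
            "basin": r.basin.value,
            "truth_status": r.truth_status.value,
            "reader": r.reader.value,
        }
        for m in METRICS:
            row[m] = metric_values(r, m)
        rows.append(row)
    return pd.DataFrame(rows)


def pivot_readers(records, metric: str) -> pd.DataFrame:
    """Paired wide view of one metric: one row per node, columns R1/R2.

    Only nodes with the metric present for both readers are returned; the
    number of dropped incomplete pairs is stored in ``df.attrs['n_dropped']``.
    """
    df = records_to_frame(records)
    wide = df.pivot_table(
        index=["patient_id", "node_id", "truth_status"],
        columns="reader",
        values=metric,
        aggfunc="first",
    ).reset_index()
    total = len(wide)
    complete = wide.dropna(subset=[c for c in ("R1", "R2") if c in wide.columns])
    if "R1" not in complete.columns or "R2" not in complete.columns:
        raise ValueError(f"both readers required to pair metric {metric!r}")
    complete = complete.rename_axis(columns=None)
    complete.attrs["n_dropped"] = total - len(complete)
    return complete
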