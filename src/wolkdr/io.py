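"""CSV/JSON readers and writers for the tabular inputs.

All formats are plain text. Genotype calls use two columns ``g1016`` and
``g1534`` with slash-separated calls ("V/V", "V/I", "F/C"); unordered, so
"I/V" is accepted and normalized.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .bioassay import DoseRecord, DoseResponseTable
from .kdr import KdrGenotype
from .monitoring import DamRecord, MtdnaScreen, TransmissionScreen, TrapWeekRecord

logger = logging.getLogger(__name__)

GENOTYPE_COLUMNS = ["sample_id", "g1016", "g1534"]
TRAP_COLUMNS = ["week", "n_tested", "n_positive"]
TRANSMISSION_COLUMNS = ["dam_id", "dam_infected", "larva_id", "larva_infected"]
BIOASSAY_COLUMNS = ["population", "compound", "dose", "n_exposed", "n_dead"]


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_call(raw: object) -> tuple[str, str] | None:
    if not isinstance(raw, str):
        return None
    parts = raw.strip().upper().split("/")
    if len(parts) != 2 or not all(parts):
        return None
    return parts[0], parts[1]


def read_genotypes(path) -> list[KdrGenotype]:
    """Read a kdr genotype table; rows with missing calls are dropped with a warning."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, GENOTYPE_COLUMNS, path)
    genos: list[KdrGenotype] = []
    for idx, row in df.iterrows():
        calls_1016 = _parse_call(row["g1016"])
        calls_1534 = _parse_call(row["g1534"])
        if calls_1016 is None or calls_1534 is None:
            logger.warning(
                "%s row %d (sample %s): missing/unparseable call, dropped",
                path, idx, row.get("sample_id", "?"),
            )
            continue
        genos.append(
            KdrGenotype(calls_1016, calls_1534, sample_id=str(row["sample_id"]))
        )
    return genos


def read_genotype_frame(path) -> pd.DataFrame:
    """Raw genotype table with optional wolbachia_status / week columns kept."""
    df = pd.read_csv(path, dtype={"sample_id": str, "g1016": str, "g1534": str})
    _require_columns(df, GENOTYPE_COLUMNS, path)
    return df


def write_genotypes(
    genos: list[KdrGenotype], path, weeks=None, wolbachia_status=None
) -> None:
    rows = {
        "sample_id": [g.sample_id for g in genos],
        "g1016": ["/".join(g.site1016) for g in genos],
        "g1534": ["/".join(g.site1534) for g in genos],
    }
    if wolbachia_status is not None:
        rows["wolbachia_status"] = list(wolbachia_status)
    if weeks is not None:
        rows["week"] = list(weeks)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trap_series(path) -> list[TrapWeekRecord]:
    df = pd.read_csv(path)
    _require_columns(df, TRAP_COLUMNS, path)
    return [
        TrapWeekRecord(int(r.week), int(r.n_tested), int(r.n_positive))
        for r in df.itertuples()
    ]


def write_trap_series(records: list[TrapWeekRecord], path) -> None:
    pd.DataFrame(
        [(r.week, r.n_tested, r.n_positive) for r in records], columns=TRAP_COLUMNS
    ).to_csv(path, index=False)


_TRUE = {"true", "1", "yes", "pos", "positive", "t"}
_FALSE = {"false", "0", "no", "neg", "negative", "f"}


def _parse_bool(raw: object, context: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"{context}: cannot parse boolean value {raw!r}")


def read_transmission_screen(path) -> TransmissionScreen:
    """Long-format screen: one row per screened larva."""
    df = pd.read_csv(path, dtype={"dam_id": str, "larva_id": str})
    _require_columns(df, TRANSMISSION_COLUMNS, path)
    dams = []
    for dam_id, group in df.groupby("dam_id", sort=True):
        status = {_parse_bool(v, f"dam {dam_id}") for v in group["dam_infected"]}
        if len(status) != 1:
            raise ValueError(f"{path}: dam {dam_id} has inconsistent infection status")
        larvae = [_parse_bool(v, f"dam {dam_id} larva") for v in group["larva_infected"]]
        dams.append(
            DamRecord(
                dam_id=str(dam_id),
                dam_infected=status.pop(),
                larvae_infected=sum(larvae),
                larvae_uninfected=len(larvae) - sum(larvae),
            )
        )
    return TransmissionScreen(tuple(dams))


def write_transmission_screen(screen: TransmissionScreen, path) -> None:
    rows = []
    for dam in screen.dams:
        for i in range(dam.larvae_infected):
            rows.append((dam.dam_id, dam.dam_infected, f"{dam.dam_id}-L{i}", True))
        for i in range(dam.larvae_uninfected):
            rows.append(
                (dam.dam_id, dam.dam_infected, f"{dam.dam_id}-U{i}", False)
            )
    pd.DataFrame(rows, columns=TRANSMISSION_COLUMNS).to_csv(path, index=False)


def read_mtdna_screen(path) -> MtdnaScreen:
    with open(path) as fh:
        d = json.load(fh)
    return MtdnaScreen(
        n_tested=int(d["n_tested"]),
        n_marked=int(d["n_marked"]),
        n_marked_negative=int(d["n_marked_negative"]),
    )


def write_mtdna_screen(screen: MtdnaScreen, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_tested": screen.n_tested,
                "n_marked": screen.n_marked,
                "n_marked_negative": screen.n_marked_negative,
            },
            indent=2,
        )
    )


def read_bioassays(path) -> list[DoseResponseTable]:
    """One table per (population, compound) group."""
    df = pd.read_csv(path, dtype={"population": str, "compound": str})
    _require_columns(df, BIOASSAY_COLUMNS, path)
    tables = []
    for (pop, compound), group in df.groupby(["population", "compound"], sort=True):
        records = tuple(
            DoseRecord(float(r.dose), int(r.n_exposed), int(r.n_dead))
            for r in group.itertuples()
        )
        tables.append(DoseResponseTable(str(pop), str(compound), records))
    return tables


def write_bioassays(tables: list[DoseResponseTable], path) -> None:
    rows = [
        (t.population, t.compound, r.dose, r.n_exposed, r.n_dead)
        for t in tables
        for r in t.records
    ]
    pd.DataFrame(rows, columns=BIOASSAY_COLUMNS).to_csv(path, index=False)
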