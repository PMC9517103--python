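"""CSV / JSON-lines persistence for registries, jobs, ledger and audit log.

Sites and workers are RFC-4180 CSV (UTF-8, mandatory header); jobs, ledger
entries and audit records are JSON lines, which keeps the ledger and audit
log append-only friendly.  Malformed rows are rejected with line-numbered
errors, never silently skipped, and every load/save pair is a lossless
round-trip — dose floats are serialised with full precision (repr) so they
reload bit-exact.
"""

from __future__ import annotations

import csv
import io as _io
import json
from datetime import date
from pathlib import Path

from .errors import DateFormatError, DuplicateIdError, SchemaError
from .planner import Job, JobState
from .registry import (
    LOCATION_FLAG_NAMES,
    DoseEntry,
    Ledger,
    LocationFlags,
    Worker,
    Worksite,
)

SITE_FIELDS = [
    "site_id",
    "name",
    "annual_mean_concentration",
    "measurement_start",
    "measurement_end",
    "occupancy_hours_per_year",
    *LOCATION_FLAG_NAMES,
]
WORKER_FIELDS = ["worker_id", "name", "status"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no", ""}


def _parse_bool(value: str, field: str, line: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise SchemaError(f"field {field!r}: {value!r} is not a boolean", line=line)


def _parse_date(value: str, field: str, line: int) -> date:
    try:
        return date.fromisoformat(value.strip())
    except ValueError:
        raise DateFormatError(
            f"field {field!r}: {value!r} is not an ISO-8601 date", line=line
        ) from None


def _parse_float(value: str, field: str, line: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"field {field!r}: {value!r} is not a number", line=line) from None


def _check_header(header: list[str] | None, expected: list[str], what: str) -> None:
    if header != expected:
        raise SchemaError(
            f"{what} header mismatch: expected {','.join(expected)}, "
            f"got {','.join(header) if header else '<empty file>'}",
            line=1,
        )


# -- sites -------------------------------------------------------------------


def sites_to_csv(sites: list[Worksite]) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(SITE_FIELDS)
    for s in sites:
        writer.writerow(
            [
                s.site_id,
                s.name,
                repr(s.annual_mean_concentration),
                s.measurement_start.isoformat(),
                s.measurement_end.isoformat(),
                repr(s.occupancy_hours_per_year),
                *[str(getattr(s.location_flags, f)).lower() for f in LOCATION_FLAG_NAMES],
            ]
        )
    return buf.getvalue()


def sites_from_csv(text: str) -> list[Worksite]:
    reader = csv.reader(_io.StringIO(text))
    rows = list(reader)
    _check_header(rows[0] if rows else None, SITE_FIELDS, "sites")
    sites: list[Worksite] = []
    seen: set[str] = set()
    for line_no, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(SITE_FIELDS):
            raise SchemaError(
                f"expected {len(SITE_FIELDS)} fields, got {len(row)}", line=line_no
            )
        rec = dict(zip(SITE_FIELDS, row))
        if rec["site_id"] in seen:
            raise DuplicateIdError(f"duplicate site_id {rec['site_id']!r}", line=line_no)
        seen.add(rec["site_id"])
        flags = LocationFlags(
            **{f: _parse_bool(rec[f], f, line_no) for f in LOCATION_FLAG_NAMES}
        )
        sites.append(
            Worksite(
                site_id=rec["site_id"],
                name=rec["name"],
                annual_mean_concentration=_parse_float(
                    rec["annual_mean_concentration"], "annual_mean_concentration", line_no
                ),
                measurement_start=_parse_date(
                    rec["measurement_start"], "measurement_start", line_no
                ),
                measurement_end=_parse_date(
                    rec["measurement_end"], "measurement_end", line_no
                ),
                occupancy_hours_per_year=_parse_float(
                    rec["occupancy_hours_per_year"], "occupancy_hours_per_year", line_no
                ),
                location_flags=flags,
            )
        )
    return sites


# -- workers -----------------------------------------------------------------


def workers_to_csv(workers: list[Worker]) -> str:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(WORKER_FIELDS)
    for w in workers:
        writer.writerow([w.worker_id, w.name, w.status])
    return buf.getvalue()


def workers_from_csv(text: str) -> list[Worker]:
    reader = csv.reader(_io.StringIO(text))
    rows = list(reader)
    _check_header(rows[0] if rows else None, WORKER_FIELDS, "workers")
    workers: list[Worker] = []
    seen: set[str] = set()
    for line_no, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(WORKER_FIELDS):
            raise SchemaError(
                f"expected {len(WORKER_FIELDS)} fields, got {len(row)}", line=line_no
            )
        worker_id, name, status = row
        if worker_id in seen:
            raise DuplicateIdError(f"duplicate worker_id {worker_id!r}", line=line_no)
        seen.add(worker_id)
        from . import dose_model

        if status not in dose_model.WORKER_STATUSES:
            raise SchemaError(f"field 'status': unknown status {status!r}", line=line_no)
        workers.append(Worker(worker_id=worker_id, name=name, status=status))
    return workers


# -- jobs (JSON lines) ---------------------------------------------------------


def job_to_record(job: Job) -> dict:
    return {
        "job_id": job.job_id,
        "site_id": job.site_id,
        "start_date": job.start_date.isoformat(),
        "duration": job.duration,
        "assigned_worker_ids": list(job.assigned_worker_ids),
        "state": job.state.value,
        "last_edited": job.last_edited,
    }


def job_from_record(rec: dict, line: int | None = None) -> Job:
    try:
        return Job(
            job_id=rec["job_id"],
            site_id=rec["site_id"],
            start_date=date.fromisoformat(rec["start_date"]),
            duration=float(rec["duration"]),
            assigned_worker_ids=tuple(rec["assigned_worker_ids"]),
            state=JobState(rec.get("state", "PLANNED")),
            last_edited=rec.get("last_edited"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise SchemaError(f"malformed job record: {exc}", line=line) from None


def jobs_to_jsonl(jobs: list[Job]) -> str:
    return "".join(json.dumps(job_to_record(j)) + "\n" for j in jobs)


def jobs_from_jsonl(text: str) -> list[Job]:
    jobs = []
    seen: set[str] = set()
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON: {exc}", line=line_no) from None
        job = job_from_record(rec, line=line_no)
        if job.job_id in seen:
            raise DuplicateIdError(f"duplicate job_id {job.job_id!r}", line=line_no)
        seen.add(job.job_id)
        jobs.append(job)
    return jobs


# -- ledger (JSON lines) -------------------------------------------------------


def entry_to_record(entry: DoseEntry) -> dict:
    # float -> JSON via repr keeps all 17 significant digits
    return {
        "entry_id": entry.entry_id,
        "worker_id": entry.worker_id,
        "job_id": entry.job_id,
        "dose": entry.dose,
        "attribution_year": entry.attribution_year,
        "job_date": entry.job_date.isoformat(),
    }


def ledger_to_jsonl(ledger: Ledger) -> str:
    return "".join(json.dumps(entry_to_record(e)) + "\n" for e in ledger.entries())


def ledger_from_jsonl(text: str) -> Ledger:
    ledger = Ledger()
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            entry = DoseEntry(
                entry_id=rec["entry_id"],
                worker_id=rec["worker_id"],
                job_id=rec["job_id"],
                dose=float(rec["dose"]),
                attribution_year=int(rec["attribution_year"]),
                job_date=date.fromisoformat(rec["job_date"]),
            )
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON: {exc}", line=line_no) from None
        except (KeyError, ValueError, TypeError) as exc:
            raise SchemaError(f"malformed ledger record: {exc}", line=line_no) from None
        ledger.append(entry)
    return ledger


# -- audit log (JSON lines) ----------------------------------------------------


def audit_to_jsonl(records: list[dict]) -> str:
    return "".join(json.dumps(rec) + "\n" for rec in records)


def audit_from_jsonl(text: str) -> list[dict]:
    records = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            records.append(json.loads(line))
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON: {exc}", line=line_no) from None
    return records


# -- file helpers --------------------------------------------------------------


def write_text(path: str | Path, text: str) -> None:
    Path(path).write_text(text, encoding="utf-8")


def read_text(path: str | Path) -> str:
    return Path(path).read_text(encoding="utf-8")
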