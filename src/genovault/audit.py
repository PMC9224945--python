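"""Append-only decision/audit log (JSON-lines)."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union


@dataclass
class AuditRecord:
    timestamp: float
    subject: dict
    operation: str
    target: str
    outcome: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp,
                "subject": self.subject,
                "operation": self.operation,
                "target": self.target,
                "outcome": self.outcome,
            },
            sort_keys=True,
        )


@dataclass
class AuditLog:
    """One record per authorization call; optionally mirrored to a file."""

    path: Optional[Union[str, Path]] = None
    records: list[AuditRecord] = field(default_factory=list)

    def append(self, subject: dict, operation: str, target: str, outcome: str) -> AuditRecord:
        rec = AuditRecord(time.time(), subject, operation, target, outcome)
        self.records.append(rec)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(rec.to_json() + "\n")
        return rec

    def __len__(self) -> int:
        return len(self.records)
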