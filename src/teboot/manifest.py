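"""Run manifests: everything needed to reproduce a run bit-identically."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    seed: int | None
    version: str
    config: dict = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    test_status: list[dict] = field(default_factory=list)

    def add_input(self, name: str, path: str | Path) -> None:
        self.input_checksums[name] = file_checksum(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
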