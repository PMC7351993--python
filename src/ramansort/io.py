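"""Run provenance: manifests with config echo, seed, counts and checksums."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Accumulates provenance for one run; written on success and failure."""

    def __init__(self, outdir: str | Path, config: Mapping[str, Any], seed: int):
        from . import __version__

        self.outdir = Path(outdir)
        self.data: dict[str, Any] = {
            "software": "ramansort",
            "version": __version__,
            "seed": seed,
            "config": dict(config),
            "status": "running",
            "counts": {},
            "outputs": {},
        }

    def count(self, stage: str, n: int) -> None:
        self.data["counts"][stage] = int(n)

    def register_output(self, path: str | Path) -> None:
        path = Path(path)
        self.data["outputs"][path.name] = file_sha256(path)

    def write(self, status: str = "success") -> Path:
        self.data["status"] = status
        self.outdir.mkdir(parents=True, exist_ok=True)
        target = self.outdir / "manifest.json"
        target.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return target
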