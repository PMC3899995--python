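"""Atomic text-file writes (temp file + rename on the same filesystem)."""

from __future__ import annotations

import os
import tempfile
from collections.abc import Iterable
from pathlib import Path


def atomic_write_text(path: str | os.PathLike, text: str) -> Path:
    """Write ``text`` to ``path`` atomically; never leaves a half-written file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def write_csv(path: str | os.PathLike, header: Iterable[str], rows: Iterable[Iterable]) -> Path:
    """Write a plain CSV (no quoting needed for our tables) atomically."""
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join("" if v is None else str(v) for v in row))
    return atomic_write_text(path, "\n".join(lines) + "\n")
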