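"""Flat ``key = value`` config files (guideline settings, team profiles)."""

from __future__ import annotations

from pathlib import Path


def read_flat(path: str | Path) -> dict[str, str]:
    """Read a flat key/value file: one ``key = value`` per line, ``#`` comments."""
    mapping: dict[str, str] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        mapping[key.strip()] = value.strip()
    return mapping


def write_flat(path: str | Path, mapping: dict[str, object]) -> None:
    lines = [f"{key} = {'none' if value is None else value}" for key, value in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
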