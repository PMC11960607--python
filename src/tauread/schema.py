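"""Minimal validation of report JSON against the schemas shipped with the package.

Supports the subset of JSON Schema the shipped schemas use: ``type``,
``required``, ``properties``, ``enum``, ``anyOf`` and local ``$ref`` into
``$defs``. Enough to guarantee report shape without an external dependency.
"""

from __future__ import annotations

import json
from importlib import resources

_TYPES = {
    "object": dict,
    "string": str,
    "boolean": bool,
    "integer": int,
    "number": (int, float),
    "null": type(None),
    "array": list,
}


def load_schema(name: str) -> dict:
    """Load a schema shipped under ``tauread/schemas`` by stem name."""
    text = resources.files("tauread.schemas").joinpath(f"{name}.schema.json").read_text()
    return json.loads(text)


def _check(obj, schema: dict, root: dict, path: str) -> list[str]:
    errors: list[str] = []
    if "$ref" in schema:
        ref = schema["$ref"]
        assert ref.startswith("#/$defs/"), ref
        return _check(obj, root["$defs"][ref.split("/")[-1]], root, path)
    if "anyOf" in schema:
        branches = [_check(obj, sub, root, path) for sub in schema["anyOf"]]
        if not any(not errs for errs in branches):
            errors.append(f"{path}: matches no anyOf branch")
        return errors
    if "type" in schema:
        expected = _TYPES[schema["type"]]
        ok = isinstance(obj, expected)
        if schema["type"] in ("integer", "number") and isinstance(obj, bool):
            ok = False
        if not ok:
            errors.append(f"{path}: expected {schema['type']}, got {type(obj).__name__}")
            return errors
    if "enum" in schema and obj not in schema["enum"]:
        errors.append(f"{path}: {obj!r} not in {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                errors.append(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                errors.extend(_check(obj[key], sub, root, f"{path}.{key}"))
    return errors


def validate_report(obj: dict, schema_name: str) -> None:
    """Raise ``ValueError`` listing every schema violation, if any."""
    schema = load_schema(schema_name)
    errors = _check(obj, schema, schema, schema.get("title", schema_name))
    if errors:
        raise ValueError("; ".join(errors))
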