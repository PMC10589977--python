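"""Canonical JSON serialization of analysis parameters.

Every operation recorded in the analysis log stores its parameters as a
canonical JSON document: keys sorted, no insignificant whitespace beyond
single separators, floats rendered with Python's shortest exact round-trip
representation. Two parameter sets are the same analysis step if and only
if their canonical documents are byte-identical, which is what makes the
replay-determinism guarantee well defined.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np


def _plain(obj: Any) -> Any:
    """Reduce numpy scalars/arrays and tuples to plain JSON-able Python."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def canonical_json(obj: Any) -> str:
    """Serialize ``obj`` to its canonical JSON document (a ``str``)."""
    plain = _plain(obj)
    return json.dumps(plain, sort_keys=True, separators=(",", ":"), allow_nan=False)


def from_canonical_json(doc: str) -> Any:
    return json.loads(doc)
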