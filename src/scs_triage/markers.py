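"""Explicit marker for metrics whose denominator is empty.

A sensitivity computed from a table with no reference-positive subjects is
not zero and not NaN — it is undefined, and reports must say so. The
singleton :data:`UNDEFINED` propagates through reports and serialises to
the string ``"undefined"``.
"""

from __future__ import annotations

__all__ = ["UNDEFINED", "Undefined", "is_defined"]


class Undefined:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED"

    def __bool__(self) -> bool:
        return False

    def __deepcopy__(self, memo):
        return self

    def to_json(self) -> str:
        return "undefined"


UNDEFINED = Undefined()


def is_defined(value) -> bool:
    return value is not UNDEFINED
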