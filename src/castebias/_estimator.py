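"""Minimal scikit-learn-compatible estimator protocol.

Implements ``get_params``/``set_params`` by introspecting ``__init__``
keyword arguments, which is all :func:`sklearn.base.clone`, pipelines and
the model-selection utilities need. Keeping the protocol in-house avoids a
runtime dependency on scikit-learn, which this package uses only as an
independent cross-check in its test suite.
"""

from __future__ import annotations

import inspect


class ParamsMixin:
    """get_params/set_params over the constructor signature."""

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"Invalid parameter {key!r} for estimator {type(self).__name__}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:  # sklearn-style repr
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"
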