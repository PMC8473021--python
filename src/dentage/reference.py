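"""Published reference values shipped with the package.

The original clinical study of this methodology reported three final
RBF age-estimation models together with their sensitivity rankings:

* ``combined`` — women and men, 22 inputs (X01-X21 + SEX),
  topology ``RBF 22:22-15-1:1``;
* ``female``  — women only, 13 retained inputs, ``RBF 13:13-1-1:1``;
* ``male``    — men only, 18 retained inputs, ``RBF 18:18-1-1:1``.

The quotient tables below are those published rankings, stored in
published rank order.  They are reference fixtures for the ranking and
feature-assembly machinery — the underlying clinical images are
private, so the models themselves cannot be re-fitted here.
"""

from __future__ import annotations

from importlib import resources

from .io import read_quotient_table

REFERENCE_MODELS = ("combined", "female", "male")

REFERENCE_TOPOLOGIES = {
    "combined": "RBF 22:22-15-1:1",
    "female": "RBF 13:13-1-1:1",
    "male": "RBF 18:18-1-1:1",
}


def load_reference_quotients(model: str) -> dict[str, float]:
    """Published sensitivity quotients, in published rank order."""
    if model not in REFERENCE_MODELS:
        raise KeyError(f"model must be one of {REFERENCE_MODELS}, got {model!r}")
    path = resources.files("dentage.data") / f"quotients_{model}.csv"
    with resources.as_file(path) as p:
        return read_quotient_table(p)


def reference_retained_inputs(model: str) -> list[str]:
    """The retained input set of a published model, in rank order."""
    return list(load_reference_quotients(model))
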