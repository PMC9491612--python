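"""Export a built-in model to SBML and import it back.

The reader supports the ODE-reaction core of SBML L2/L3 (species,
parameters, content-MathML kinetic laws, boundary species); everything
else is rejected explicitly rather than silently ignored.
"""

import tempfile
from pathlib import Path

import sympy as sp

from teaps import build_builtin_model, export_sbml, import_sbml

model = build_builtin_model("T8")
path = Path(tempfile.mkdtemp()) / "t8.xml"
export_sbml(model, path)
print(f"wrote {path} ({path.stat().st_size} bytes)")

back = import_sbml(path)
print(f"re-imported: {len(back.species_names)} species, "
      f"{len(back.parameter_names)} parameters")
same = all(sp.simplify(a - b) == 0 for a, b in zip(model.rhs, back.rhs))
print(f"right-hand sides symbolically identical: {same}")
print(f"constant species preserved: {back.constant_mask}")
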