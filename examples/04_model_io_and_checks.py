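"""Model I/O round trips and consistency checks.

Writes the two-cell network in all three dialects (tabular TSV, JSON, SBML
L3+fbc), reloads it, and runs the content summary and mass/charge balance
check.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from diazofba import (
    check_mass_charge_balance,
    count_unique,
    fba,
    load_model,
    make_toy_two_cell,
    write_model,
)

model, _ = make_toy_two_cell()

summary = count_unique(model)
print(f"unique template reactions: {summary.n_unique_reactions}")
print(f"vegetative {summary.n_vegetative_reactions} / heterocyst "
      f"{summary.n_heterocyst_reactions} / shared {summary.n_shared_reactions}")

imbalances = check_mass_charge_balance(model)
print(f"mass/charge imbalances: {len(imbalances)}")

with TemporaryDirectory() as tmp:
    for suffix in ("tsv", "json", "xml"):
        path = Path(tmp) / f"two_cell.{suffix}"
        write_model(model, path)
        back = load_model(path)
        if back.objective is None:  # the tabular dialect carries no objective
            back.objective = model.objective
        print(f"{suffix:4s} round trip: {len(back.reactions)} reactions, "
              f"growth {fba(back).objective_value:.6f} 1/h")
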