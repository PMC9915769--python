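"""Buried surface area of a protein-peptide style interface.

Builds a small synthetic two-chain complex, computes each chain's
solvent-accessible surface area (Shrake-Rupley, probe 1.4 Å, 960 sphere
points) and the area buried at the interface:

    BSA = SASA(A) + SASA(B) - SASA(AB).

For a real deposited co-crystal (PDB or mmCIF file on disk), the same
computation is exposed as

    proppd bsa --structure 8FE7.cif --group-a A --group-b E

with explicit chain selection, since crystals often carry several copies of
the complex per asymmetric unit.
"""

import gemmi
import numpy as np

from proppd import buried_surface_area

st = gemmi.Structure()
model = gemmi.Model("1")
rng = np.random.default_rng(7)
for chain_name, z in (("A", 0.0), ("B", 2.6)):
    chain = gemmi.Chain(chain_name)
    for i in range(8):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i + 1, " ")
        for j in range(3):
            atom = gemmi.Atom()
            atom.name = "C"
            atom.element = gemmi.Element("C")
            jitter = rng.normal(scale=0.2, size=3)
            atom.pos = gemmi.Position(
                i * 1.8 + jitter[0], j * 1.8 + jitter[1], z + jitter[2]
            )
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
st.add_model(model)

result = buried_surface_area(st, ["A"], ["B"])
print(f"SASA(A)  = {result.sasa_A:8.1f} A^2")
print(f"SASA(B)  = {result.sasa_B:8.1f} A^2")
print(f"SASA(AB) = {result.sasa_AB:8.1f} A^2")
print(f"BSA      = {result.bsa:8.1f} A^2")
# The buried area is the surface each chain loses on complex formation;
# transient peptide-mediated interfaces typically bury ~1,000-1,500 A^2.
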