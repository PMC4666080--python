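"""Parse a secondary structure and inspect its elastic network.

Builds the yeast tRNA-phe cloverleaf, prints the helix/loop segmentation
and the spring census.  The counts follow the connectivity rules: inside a
helix each bead is sprung to its first/second/third strand neighbours, its
base-pair partner and the partner's first neighbours; hairpin-loop beads
carry only backbone springs; hinge and tail beads also get bending/torsion
springs so the junction holds the arms' arrangement.
"""

from collections import Counter

import rnabd as rb

ss, arms = rb.load_fixture("trna_phe")
print(f"{ss.n_residues} nucleotides, {ss.n_helices} helices")
for h in ss.helices:
    print(f"  {h.name:16s} {h.a_start:3d}-{h.a_end:<3d} : "
          f"{h.b_start:3d}-{h.b_end:<3d}  ({h.n_bp} bp)")
for face in ss.loop_faces():
    if face["beads"]:
        residues = ",".join(str(b + 1) for b in face["beads"])
        print(f"  {face['kind']:9s} residues {residues}")

net = rb.build_spring_network(ss)
conf = rb.assemble_initial_conformation(ss, seed=0)
net = rb.assign_equilibrium_lengths(net, conf.coords)
print(f"\n{len(net.springs)} springs:", dict(Counter(s.kind for s in net.springs)))
print(f"initial conformation Rg = {rb.radius_of_gyration(conf):.1f} A")
# a backbone spring inside a helix rests at the A-form chord, ~= 2 sigma
bb = next(s for s in net.springs if s.kind == "backbone" and s.j < 7)
print(f"helix backbone rest length {bb.l_e:.2f} A (touching beads: "
      f"{rb.DEFAULT_PARAMS.l_e1:.2f} A)")
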