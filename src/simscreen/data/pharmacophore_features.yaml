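# Pharmacophoric feature definitions (version 1).
#
# Curated single-purpose SMARTS in the spirit of the Gobbi-Poppinger feature
# set: six feature classes typed by substructure rules.  A feature point is
# the full set of atoms matched by one SMARTS hit; topological distances
# between feature points are measured as the minimum shortest-path distance
# between their atom sets, which makes the encoding independent of input
# atom order.  Edit with care: changing a rule changes every stored
# 2D-pharmacophore and reduced-graph fingerprint.
version: 1
features:
  donor:
    - "[N;!H0;v3]"
    - "[N;!H0;+1;v4]"
    - "[O,S;H1;+0]"
    - "[n;H1;+0]"
  acceptor:
    - "[O;X2;H0;+0]"
    - "[O;X1;+0]"
    - "[O;-]"
    - "[N;X3;H0;v3;+0;!$(N-*=[O,N,S])]"
    - "[N;X2,X1;H0;+0;!$(N=O)]"
    - "[n;X2;H0;+0]"
  cation:
    - "[+;!$([+]~[-])]"
    - "[N;X3;H2;+0;$(N-[C;X4])]"
  anion:
    - "[-;!$([-]~[+])]"
    - "[O;H1;$(O-[C,S,P]=O)]"
  aromatic:
    - "a1aaaaa1"
    - "a1aaaa1"
  hydrophobic:
    - "[C;X4;H3;$(C-[C;X4]-[C;X4])]"
    - "[Cl,Br,I;$(*-[#6])]"
    - "[S;X2;H0;$(S(-[C;X4])-[C;X4])]"
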