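# Default building-block library: 11 monocycles with their ring-fusion
# transformations.  Every transformation annulates a new ring across a C-C
# bond whose two carbons each belong to exactly one ring, so growth is
# cata-condensed and heteroatoms never sit on a fused bond.
#
# weight: sampling weight used during randomized generation (benzene is
# favoured 10:1 over every other block).
blocks:
  - key: benzene
    parent_smiles: c1ccccc1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:2]:1:[c:1]:[c:3]:[c:4]:[c:5]:[c:6]:1"
    ring_size: 6
    weight: 10
  - key: pyridine
    parent_smiles: c1ccncc1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:6]:1:[c:2]:[c:1]:[n:3]:[c:4]:[c:5]:1"
    ring_size: 6
    weight: 1
  - key: pyrazine
    parent_smiles: c1cnccn1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:2]:1:[c:1]:[n:3]:[c:4]:[c:5]:[n:6]:1"
    ring_size: 6
    weight: 1
  - key: borinine
    parent_smiles: B1=CC=CC=C1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[#5;a:3]:1:[c:1]:[c:2]:[#6;a:6]:[c:5]:[c:4]:1"
    ring_size: 6
    weight: 1
  - key: 14diborinine
    parent_smiles: B1=CC=BC=C1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[#5;H0;a:6]:1:[#6:2]:[#6:1]:[#5;H0;a:3]:[#6:4]:[#6:5]:1"
    ring_size: 6
    weight: 1
  - key: dhdiborinine
    parent_smiles: B1C=CBC=C1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[H][#5:3]-1-[c:1][c:2]-[#5:6]([H])-[c:5][c:4]-1"
    ring_size: 6
    weight: 1
  - key: borole
    parent_smiles: B1C=CC=C1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:2]:1:[c:5]:[c:4]:[b:3]([H]):[c:1]:1"
    ring_size: 5
    weight: 1
  - key: pyrrole
    parent_smiles: c1cc[nH]c1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:2]:1:[c:5]:[c:4]:[n:3]([H]):[c:1]:1"
    ring_size: 5
    weight: 1
  - key: furan
    parent_smiles: c1ccoc1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:2]:1:[c:5]:[c:4]:[o:3]:[c:1]:1"
    ring_size: 5
    weight: 1
  - key: thiophene
    parent_smiles: c1ccsc1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:2]:1:[c:5]:[c:4]:[s:3]:[c:1]:1"
    ring_size: 5
    weight: 1
  - key: cyclobutadiene
    parent_smiles: C1=CC=C1
    fusion_smarts: "[#6;R1:1]~[#6;R1:2]>>[c:1]1[c:2][c:4][c:3]1"
    ring_size: 4
    weight: 1
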