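# Reference crystal structures

The coordinate-based R_g checks look here for locally supplied PDB/mmCIF
files (not redistributed with the package):

- `4f5s.cif` (or `.pdb`) — bovine serum albumin; chain A is used as the
  monomer reference (R_g ≈ 27.1 Å, electron-weighted, in vacuo).
- `4v1w.cif` — apoferritin 24-mer (R_g ≈ 54.0 Å).

Download them from https://www.rcsb.org and drop them in this directory to
enable `tests/test_acceptance.py::TestCrystalReferenceRg`.
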