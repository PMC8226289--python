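"""Score entropy-based binding-site predictions against a complex
structure.

Contacts are receptor residues with any heavy atom within 4.5 A of the
ligand.  Predicting "residues whose column entropy >= cutoff" and
sweeping the cutoff traces precision and recall; the useful range in
practice lies between ~0.8 bits (maximal recall) and ~1.8 bits
(improving precision).
"""

from nlrdiv import (
    Alignment,
    AlignedSeq,
    contacts_from_structure,
    make_toy_complex,
    precision_recall,
    profile_alignment,
    write_attribute_file,
)

# 12-residue receptor; residues 3,4 are highly diverse (2 bits), 7,8
# mildly diverse (1 bit), the rest invariant
variants = ["AR", "CK", "DE", "EW"]
mild = ["ST", "ST", "AV", "AV"]
seqs = []
for v1, v2 in zip(variants, mild):
    seq = list("MKAAASLAAAQL")
    seq[2], seq[3] = v1[0], v1[1]
    seq[6], seq[7] = v2[0], v2[1]
    seqs.append("".join(seq))
aln = Alignment(records=[AlignedSeq(f"eco{i}|r", f"eco{i}", s)
                         for i, s in enumerate(seqs)], reference_id="eco0|r")
profile = profile_alignment(aln)

model, _ = make_toy_complex(n_receptor_res=12, contact_positions=(3, 4, 5))
truth = contacts_from_structure(model, "A", "B", cutoff=4.5)
print("structural contacts:", sorted(truth.contacts))

curve = precision_recall(profile, {i: i for i in range(1, 13)}, truth,
                         cutoffs=[0.5, 1.0, 1.5, 2.0])
print(curve.to_frame().to_string(index=False))
# At low cutoffs everything diverse is predicted (high recall, modest
# precision); raising the cutoff trades recall for precision.

write_attribute_file({r: float(profile.entropy[r - 1]) for r in range(1, 13)},
                     "chimera", "scratch_entropy.defattr")
print("wrote Chimera attribute file scratch_entropy.defattr")
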