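# Default toe digitization template: 19 fixed landmarks and 13 curves.
#
# Fixed landmarks (1-based, odd = left side of toe, even = right side):
#   1, 2   base of the toe where it joins the palm (left, right)
#   3, 4   proximal end of the toepad where it begins to widen (left, right)
#   5, 6   widest points of the toepad (left, right)
#   7, 8   distal end of the toepad (left, right)
#   9      tip of the toe at the ventral proximal base of the claw
#   10-19  left/right edges of five focal lamellae, numbered distal
#          to proximal in pairs (10,11), (12,13), ... (18,19)
#
# Curves are digitized with 10 points each; the first and last point of a
# curve coincide with its anchor landmarks and are dropped early in the
# analysis, leaving 8 semilandmarks per curve.
n_fixed: 19
n_semilandmarks_raw: 10
curves:
  # Eight curves outlining the toe, running proximal-left -> tip -> proximal-right.
  - {start: 1, end: 3, role: toe_outline}
  - {start: 3, end: 5, role: toe_outline}
  - {start: 5, end: 7, role: toe_outline}
  - {start: 7, end: 9, role: toe_outline}
  - {start: 9, end: 8, role: toe_outline}
  - {start: 8, end: 6, role: toe_outline}
  - {start: 6, end: 4, role: toe_outline}
  - {start: 4, end: 2, role: toe_outline}
  # Five curves tracing the free (distal) edge of each focal lamella.
  - {start: 10, end: 11, role: lamella_edge}
  - {start: 12, end: 13, role: lamella_edge}
  - {start: 14, end: 15, role: lamella_edge}
  - {start: 16, end: 17, role: lamella_edge}
  - {start: 18, end: 19, role: lamella_edge}
# Left/right landmark pairs of the focal lamellae, distal to proximal.
lamella_pairs: [[10, 11], [12, 13], [14, 15], [16, 17], [18, 19]]
# Adjacent-landmark pairs averaged for lamella height (proximal-distal spacing).
lamella_height_pairs:
  [[10, 12], [12, 14], [14, 16], [16, 18], [11, 13], [13, 15], [15, 17], [17, 19]]
# Closed toepad outline used for the landmark-based area estimate: fixed
# landmarks interleaved with the semilandmarks of the connecting curves.
pad_outline_landmarks: [3, 5, 7, 9, 8, 6, 4]
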