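# Default 18-region pain-mannequin map: 4 axial/midline regions plus 7
# bilateral pairs.  Attributes drive the ACR-1990 widespread-pain rule
# (axial + both sides + both body halves); low back counts as lower-half.
regions:
  - {id: head,           axial: true,  side: midline, body_half: upper}
  - {id: neck,           axial: true,  side: midline, body_half: upper}
  - {id: upper_back,     axial: true,  side: midline, body_half: upper}
  - {id: lower_back,     axial: true,  side: midline, body_half: lower}
  - {id: shoulder_l,     axial: false, side: left,    body_half: upper}
  - {id: shoulder_r,     axial: false, side: right,   body_half: upper}
  - {id: elbow_l,        axial: false, side: left,    body_half: upper}
  - {id: elbow_r,        axial: false, side: right,   body_half: upper}
  - {id: wrist_hand_l,   axial: false, side: left,    body_half: upper}
  - {id: wrist_hand_r,   axial: false, side: right,   body_half: upper}
  - {id: hip_l,          axial: false, side: left,    body_half: lower}
  - {id: hip_r,          axial: false, side: right,   body_half: lower}
  - {id: thigh_l,        axial: false, side: left,    body_half: lower}
  - {id: thigh_r,        axial: false, side: right,   body_half: lower}
  - {id: knee_l,         axial: false, side: left,    body_half: lower}
  - {id: knee_r,         axial: false, side: right,   body_half: lower}
  - {id: ankle_foot_l,   axial: false, side: left,    body_half: lower}
  - {id: ankle_foot_r,   axial: false, side: right,   body_half: lower}
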