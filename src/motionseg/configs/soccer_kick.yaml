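name: soccer_kick
phases:
- name: last_step          # last step of the kicking leg before impact
  start: LS1               # landing of the kicking leg
  performing: LS2
  end: LS3                 # toe-off of the kicking leg
- name: backswing
  start: LS3
  performing: LS4
  end: LS5                 # maximum hip extension
- name: leg_acceleration
  start: LS5
  performing: LS6
  end: LS7                 # ball impact
- name: follow_through
  start: LS7
  performing: LS8
  end: LS9                 # toe speed inflection
- name: landing
  start: LS9
  performing: LS10
  end: LS11                # end of kicking
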