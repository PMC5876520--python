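name: two_hand_throw
phases:
- name: windup
  start: LT1               # ready
  performing: LT2
  end: LT3                 # two hands behind the head
- name: arms_forward
  start: LT3
  performing: LT4
  end: LT5                 # maximum arm stretch
- name: follow_through
  start: LT5
  performing: LT6
  end: LT7                 # end of throwing
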