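apex
appendix
area
band
base
belt
body
cavity
cell
center
centre
chamber
component
concavity
content
crack
edge
element
end
face
groove
layer
line
margin
middle
notch
part
pore
portion
projection
protuberance
remnant
section
side
stratum
surface
tip
wall
zone
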