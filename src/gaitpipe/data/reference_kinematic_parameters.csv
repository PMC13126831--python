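group,joint,side,min_deg,max_deg,rom_deg
JIA,hip,left,-7.5,27.0,34.5
JIA,knee,left,8.4,57.4,49.0
JIA,ankle,left,-15.9,5.5,21.4
JIA,hip,right,-9.2,24.2,33.4
JIA,knee,right,6.7,55.8,49.1
JIA,ankle,right,-16.7,4.9,21.6
Arthritis,hip,left,-7.7,25.6,33.3
Arthritis,knee,left,8.8,54.9,46.1
Arthritis,ankle,left,-14.4,4.2,18.6
Arthritis,hip,right,-9.1,24.8,33.9
Arthritis,knee,right,8.3,54.8,46.5
Arthritis,ankle,right,-13.4,4.3,17.7
TD,hip,left,-7.4,25.4,32.8
TD,knee,left,6.5,55.9,49.4
TD,ankle,left,-14.1,5.3,19.4
TD,hip,right,-9.1,24.8,33.9
TD,knee,right,5.9,56.2,50.3
TD,ankle,right,-15.7,4.6,20.3
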