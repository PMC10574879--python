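species,tubercle,W,H,S,max_curvature,mean_curvature,ratio
S. bupleuroides,1,87,15,34.5,32.1,14.9,2.2
S. bupleuroides,2,68,17,50.0,45.7,28.5,1.6
S. bupleuroides,3,91,21,46.2,29.8,20.7,1.4
S. bupleuroides,4,89,23,51.7,24.2,15.7,1.5
S. bupleuroides,5,91,20,44.0,36.1,19.0,1.9
S. bupleuroides,6,90,16,35.6,28.4,18.8,1.5
S. chlorantha,1,64,18,56.3,35.2,20.9,1.7
S. chlorantha,2,54,20,74.1,29.9,19.0,1.6
S. chlorantha,3,45,12,53.3,43.6,19.6,1.6
S. chlorantha,4,57,12,42.1,26.1,13.6,1.8
S. chlorantha,5,76,19,50.0,27.4,12.6,1.7
S. chlorantha,6,73,18,49.3,39.9,16.8,2.4
S. frivaldskiana,1,65,11,32.9,35.7,22.0,1.6
S. frivaldskiana,2,73,9,25.5,32.1,20.2,1.6
S. frivaldskiana,3,83,14,34.3,31.5,21.0,1.5
S. frivaldskiana,4,63,15,47.0,22.6,19.4,1.2
S. frivaldskiana,5,77,10,26.7,22.0,18.1,1.2
S. frivaldskiana,6,74,12,31.5,28.7,22.7,1.3
S. integripetala,1,61,16,52.5,39.4,28.0,1.4
S. integripetala,2,81,22,54.3,23.9,20.7,1.2
S. integripetala,3,88,25,56.8,25.4,19.9,1.3
S. integripetala,4,96,23,47.9,23.2,12.9,1.8
S. integripetala,5,98,22,44.9,20.9,10.9,1.9
S. integripetala,6,79,22,55.7,23.9,18.6,1.3
S. spinescens,1,78,18,46.2,65.4,35.9,1.8
S. spinescens,2,71,27,76.1,150.4,69.0,2.2
S. spinescens,3,75,30,80.0,100.9,55.1,1.8
S. spinescens,4,73,26,71.2,85.7,57.8,1.5
S. spinescens,5,74,21,56.8,61.7,45.2,1.4
S. spinescens,6,80,20,50.0,47.3,25.3,1.9
S. squamigera subsp. vesiculifera,1,92,20,43.5,52.1,33.7,1.5
S. squamigera subsp. vesiculifera,2,81,18,44.4,57.6,43.3,1.3
S. squamigera subsp. vesiculifera,3,91,23,50.5,97.3,52.1,1.9
S. squamigera subsp. vesiculifera,4,86,18,41.9,147.0,46.2,3.2
S. squamigera subsp. vesiculifera,5,86,19,44.2,117.4,33.6,3.5
S. squamigera subsp. vesiculifera,6,92,15,32.6,89.7,35.4,2.5
S. gigantea,1,65,14,43.1,41.0,31.1,1.3
S. gigantea,2,61,17,55.7,51.5,37.2,1.4
S. gigantea,3,62,15,48.4,41.6,31.4,1.3
S. gigantea,4,67,14,41.8,27.2,21.7,1.3
S. gigantea,5,81,16,39.5,90.2,32.5,2.8
S. gigantea,6,67,27,80.6,114.3,29.5,3.9
S. aprica subsp. oldhamiana,1,75,59,157.3,120.5,37.1,3.2
S. aprica subsp. oldhamiana,2,76,64,168.4,160.5,30.8,5.2
S. aprica subsp. oldhamiana,3,77,55,142.9,80.9,33.3,2.4
S. aprica subsp. oldhamiana,4,73,53,145.2,88.6,37.4,2.4
S. aprica subsp. oldhamiana,5,62,42,135.5,123.5,40.2,3.1
S. aprica subsp. oldhamiana,6,54,43,159.3,90.2,39.9,2.3
S. caroliniana,1,79,32,81.0,78.3,23.6,3.3
S. caroliniana,2,74,15,40.5,44.2,17.7,2.5
S. caroliniana,3,59,26,88.1,72.6,29.9,2.4
S. caroliniana,4,64,35,109.4,172.3,37.7,4.6
S. caroliniana,5,69,29,84.1,110.5,25.2,4.4
S. caroliniana,6,54,29,107.4,146.7,31.9,4.6
S. ciliata,1,69,34,99.9,74.4,43,1.7
S. ciliata,2,49,28,116.3,67.7,58,1.8
S. ciliata,3,48,23,95.8,42.9,34,1.3
S. ciliata,4,61,30,98.0,67.2,45,1.5
S. ciliata,5,73,33,91.5,41.8,32,1.3
S. ciliata,6,73,42,115.5,83.7,44,1.9
S. yunnanensis,1,53,27,101.9,202.5,72.5,2.8
S. yunnanensis,2,66,71,215.2,149.8,54.5,2.7
S. yunnanensis,3,35,69,394.3,178.6,42.2,4.2
S. yunnanensis,4,31,58,374.2,179.6,65.0,2.8
S. yunnanensis,5,31,43,277.4,341.2,107.2,3.2
S. yunnanensis,6,37,57,308.1,234.2,66.5,3.5
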