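species,type,subgenus,section,n_tubercles,n_seeds,W_mean,W_cv,W_min,W_max,H_mean,H_cv,H_min,H_max,S_mean,S_cv,S_min,S_max,max_curvature_mean,max_curvature_cv,max_curvature_min,max_curvature_max,mean_curvature_mean,mean_curvature_cv,mean_curvature_min,mean_curvature_max,ratio_mean,ratio_cv,ratio_min,ratio_max
S. acutifolia,rugose,Behenantha,Acutifoliae,22,2,92.3,17.4,68.6,127.0,28.0,21.1,18.9,41.8,61.5,20.1,41.9,89.7,51.0,10.9,43.7,64.8,33.2,15.5,17.9,42.7,1.6,23.8,1.1,3.0
S. bupleuroides,rugose,Silene,Sclerocalycinae,18,2,88.6,16.8,53.2,115.5,20.8,27.9,10.9,34.9,46.6,15.6,34.5,60.4,30.7,29.2,17.0,49.2,18.5,27.5,9.8,28.5,1.7,17.9,1.3,2.5
S. caryophylloides,rugose,Silene,Auriculatae,20,2,91.8,21.8,60.4,129.0,26.4,24.3,12.7,40.0,57.4,12.3,42.0,71.1,40.3,16.3,23.7,50.0,32.9,18.2,19.9,42.0,1.2,10.8,1.1,1.5
S. chlorantha,rugose,Silene,Siphonomorpha,20,2,76.1,19.5,45.0,95.8,23.2,30.2,12.0,36.9,60.3,19.2,37.9,77.8,31.4,18.4,22.2,43.0,18.9,19.7,12.6,24.6,1.7,23.7,1.2,2.8
S. chlorifolia,rugose,Silene,Sclerocalycinae,10,1,98.5,10.7,79.0,117.3,26.4,18.5,14.5,31.7,53.7,18.3,32.5,67.6,29.6,36.7,17.8,57.2,15.1,14.0,11.2,17.9,1.9,29.6,1.2,3.2
S. dinarica,rugose,Silene,Siphonomorpha,18,3,86.1,13.7,64.8,108.4,20.4,18.2,13.9,26.2,47.5,16.4,35.0,66.1,42.5,34.2,28.0,73.0,32.8,26.9,23.1,56.0,1.3,11.0,1.1,1.6
S. foliosa,rugose,Silene,Siphonomorpha,16,2,85.2,18.0,60.8,108.0,26.2,34.9,13.6,42.0,60.7,23.6,33.3,86.6,32.2,27.7,20.6,55.2,21.8,23.4,11.4,34.1,1.5,20.5,1.2,2.3
S. frivaldskiana,rugose,Silene,Siphonomorpha,18,2,71.8,12.5,55.4,87.7,12.2,21.9,9.3,17.4,34.3,23.5,24.9,50.7,30.4,30.4,19.5,56.2,18.8,22.0,9.6,29.8,1.6,21.4,1.2,2.7
S. gigantea,rugose,Silene,Siphonomorpha,10,1,66.0,8.9,61.0,81.0,16.6,22.8,14.0,27.0,50.5,23.0,39.5,80.6,51.3,59.1,18.0,114.0,28.6,29.3,14.0,37.0,1.8,50.3,1.1,3.9
S. inaperta,rugose,Silene,Muscipula,19,2,45.0,16.8,31.1,63.0,9.5,18.2,6.8,12.9,42.5,15.4,32.6,53.9,54.1,37.1,18.0,112.0,39.6,28.2,14.0,58.0,1.4,31.6,1.1,2.8
S. integripetala,rugose,Behenantha,Sedoides,13,1,86.4,12.8,61.0,104.9,22.5,12.5,16.0,27.7,52.4,11.1,43.9,66.3,23.7,26.3,14.5,39.4,16.7,30.6,10.0,28.0,1.4,11.7,1.1,1.7
S. koreana,rugose,Silene,Siphonomorpha,12,1,73.1,19.3,50.0,94.0,17.8,41.2,8.0,31.0,46.9,26.4,24.2,66.7,32.9,31.9,17.0,53.9,22.7,32.4,9.4,34.5,1.4,46.6,1.0,3.7
S. linicola,rugose,Silene,Lasiocalycinae,20,2,95.4,11.9,80.0,115.0,22.9,17.3,16.0,29.0,48.2,17.5,33.7,62.7,40.0,27.2,21.9,58.3,25.5,26.2,16.7,41.1,1.6,23.0,1.2,2.6
S. marizii,rugose,Behenantha,Melandrium,6,1,138.7,15.0,118.0,174.0,19.5,21.0,15.0,26.0,28.0,8.9,24.2,30.0,33.3,18.9,26.0,43.0,20.2,37.0,14.3,33.6,1.7,15.9,1.3,2.0
S. nocturna,rugose,Silene,Silene,6,1,54.7,14.5,45.0,64.0,13.5,16.7,10.0,16.0,49.3,5.7,44.4,53.1,30.3,17.4,24.9,39.1,12.7,9.9,10.6,14.0,2.4,17.7,2.0,3.0
S. otites,rugose,Silene,Siphonomorpha,6,1,93.2,10.7,78.0,109.0,16.2,32.8,11.0,24.0,34.2,24.3,24.4,44.0,75.6,30.4,46.5,103.9,47.7,33.0,24.8,62.7,1.7,29.2,1.3,2.6
S. paradoxa,rugose,Silene,Siphonomorpha,10,1,88.7,9.6,78.0,101.0,23.2,14.6,20.0,29.0,52.3,12.1,45.5,63.0,54.7,25.2,45.0,80.0,35.3,4.4,33.1,36.8,1.5,22.3,1.3,2.2
S. pygmaea,rugose,Silene,Auriculatae,6,1,97.3,10.3,82.0,108.0,20.2,29.3,11.0,26.0,41.2,24.7,22.5,48.5,43.4,19.6,34.8,59.0,29.6,12.5,23.8,34.3,1.5,19.1,1.2,1.9
S. regia,rugose,Behenantha,Physolychnis,6,1,91.7,4.7,86.0,96.0,16.2,23.9,12.0,21.0,35.1,20.9,25.5,43.8,46.5,9.5,40.2,53.9,36.3,8.4,32.3,40.5,1.3,10.2,1.2,1.4
S. spinescens,rugose,Silene,Siphonomorpha,6,1,75.2,4.4,71.0,80.0,23.7,19.8,18.0,30.0,63.4,22.5,46.2,80.0,85.2,43.5,47.3,150.4,48.1,33.0,25.3,69.0,1.8,16.7,1.4,2.2
S. squamigera subsp. vesiculifera,rugose,Silene,Lasiocalycinae,6,1,88.0,5.0,81.0,92.0,18.8,14.0,15.0,23.0,42.9,13.6,32.6,50.6,77.4,56.6,40.4,147.0,32.0,30.2,13.3,40.3,2.5,45.7,1.4,3.9
S. aprica subsp. oldhamiana,echinate,Behenantha,Physolychnis,12,2,61.0,20.5,42.2,77.0,49.3,15.5,40.8,64.0,164.4,12.3,135.5,206.6,104.2,25.1,77.0,167.7,38.4,22.1,27.0,58.0,2.9,39.0,1.7,5.4
S. behen,echinate,Behenantha,Behenantha,14,2,84.5,15.7,61.5,101.7,77.3,23.4,42.0,100.0,182.8,18.8,133.3,229.9,199.9,67.5,86.1,447.0,49.1,15.0,39.0,66.0,4.4,79.5,1.7,10.9
S. caroliniana,echinate,Behenantha,Physolychnis,22,2,72.5,22.9,53.0,108.1,32.8,31.9,15.0,56.0,90.6,20.6,40.5,123.1,108.5,24.3,62.5,172.0,20.5,42.4,6.7,41.3,6.1,52.1,3.1,18.4
S. ciliata,echinate,Silene,Silene,20,2,64.9,15.7,48.0,83.9,32.8,21.6,20.3,45.6,101.1,15.4,62.3,128.1,78.5,28.9,42.0,126.0,38.7,19.2,28.7,57.7,2.1,27.4,1.2,3.3
S. dichotoma,echinate,Behenantha,Dichotomae,13,2,81.2,14.3,60.9,94.3,35.1,18.8,23.2,46.9,86.8,15.3,64.9,108.2,62.6,18.1,49.2,84.1,40.6,17.5,32.7,53.8,1.6,14.7,1.2,2.0
S. fabaria,echinate,Behenantha,Behenantha,6,2,84.5,10.8,74.0,97.0,71.2,13.2,59.0,83.0,168.3,6.8,156.5,185.2,161.2,21.4,110.0,202.0,78.5,13.1,68.0,92.0,2.1,20.4,1.6,2.8
S. longicilia,echinate,Silene,Siphonomorpha,25,1,70.9,15.7,42.0,87.0,23.7,30.9,13.0,36.0,67.3,29.4,40.0,120.0,81.5,50.7,17.3,167.0,40.5,29.0,20.2,64.1,2.0,33.6,0.3,3.3
S. petersonii,echinate,Behenantha,Physolychnis,4,2,68.0,10.5,61.0,78.0,83.3,13.4,71.0,98.0,247.8,20.5,212.8,321.3,191.5,11.7,178.0,225.0,79.6,17.2,60.3,89.6,2.4,16.1,2.1,3.0
S. samojedorum,echinate,Behenantha,Physolychnis,6,2,91.2,25.5,72.0,127.0,65.2,21.2,52.0,87.0,146.6,19.2,100.0,175.0,219.2,37.6,143.0,337.0,91.5,28.0,71.0,126.7,2.4,25.1,1.8,3.4
S. yunnanensis,echinate,Behenantha,Cucubaloides,6,1,42.2,33.8,31.0,66.0,54.2,30.8,27.0,71.0,278.5,38.9,101.9,394.3,214.3,31.8,149.8,341.2,68.0,32.4,42.2,107.2,3.2,18.3,2.8,4.2
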