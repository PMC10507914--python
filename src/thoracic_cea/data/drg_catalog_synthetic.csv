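drg_code,label,total_cost,operating_room_cost,national_mean_los
04C021,"Major surgery on the thorax, level 1",9000.00,2385.00,7.0
04C022,"Major surgery on the thorax, level 2",12600.00,2385.00,10.0
04C023,"Major surgery on the thorax, level 3",17000.00,2385.00,14.0
04C024,"Major surgery on the thorax, level 4",24000.00,2385.00,19.0
0403B1,"Malignant tumours of the respiratory system, rehabilitation, level 1",6222.20,0.00,25.0
04M052,"Pneumonia and pleurisy",4205.00,0.00,7.0
04M132,"Pleural effusion",3790.00,0.00,5.0
04C052,"Thoracic drainage and re-intervention procedures",5150.00,0.00,6.0
05M092,"Cardiac complication",4100.00,0.00,6.0
23M062,"Signs, symptoms and other post-surgical admissions",2300.00,0.00,3.0
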